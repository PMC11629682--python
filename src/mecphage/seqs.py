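"""Low-level nucleotide sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 2-bit codes: A=0 C=1 G=2 T=3; anything else (N etc.) -> 255
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[ord(chr(_b).lower())] = _i

_DECODE = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 2-bit codes; non-ACGT become 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    return bytes(codes).translate(_DECODE).decode("ascii")


def random_seq(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform A/C/G/T sequence."""
    return codes_to_seq(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """Apply i.i.d. per-base substitutions at ``rate``.

    Substituted positions always change to a *different* base. Returns the
    mutated sequence and the array of substituted positions (the mutation
    mask), which tests use as an exact identity oracle.
    """
    if rate <= 0:
        return seq, np.empty(0, dtype=np.int64)
    codes = seq_to_codes(seq).copy()
    hit = np.flatnonzero(rng.random(len(codes)) < rate)
    hit = hit[codes[hit] != 255]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return codes_to_seq(codes), hit


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a single master seed."""
    import zlib

    return np.random.default_rng([seed, zlib.crc32(name.encode())])
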