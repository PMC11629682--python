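"""CRISPR array detection by a CRT-style seed-and-extend scan.

The detector finds short exact seed words recurring at spacings compatible
with a repeat-spacer period, chains them, extends the repeat boundaries by
column-wise majority agreement, and validates candidate arrays against the
CRT defaults: >= 3 repeats, repeat length in [23, 47], spacer lengths in
[26, 50], mean pairwise repeat identity >= 0.9 and mean pairwise spacer
identity <= 0.62. Detection is strand-naive: an array on either strand is
reported in forward-strand coordinates.

Coordinates are 0-based half-open internally; the GFF3 export converts to
1-based inclusive.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class CrisprParams:
    seed_length: int = 8
    min_repeats: int = 3
    min_repeat_length: int = 23
    max_repeat_length: int = 47
    min_spacer_length: int = 26
    max_spacer_length: int = 50
    min_repeat_identity: float = 0.9
    max_spacer_identity: float = 0.62
    extension_agreement: float = 0.75

    @property
    def min_period(self) -> int:
        return self.min_repeat_length + self.min_spacer_length

    @property
    def max_period(self) -> int:
        return self.max_repeat_length + self.max_spacer_length


@dataclass
class CrisprArray:
    bin_id: str
    contig_id: str
    start: int  # 0-based half-open span on the contig
    end: int
    repeat_consensus: str
    repeats: list[tuple[int, str]]  # (start, sequence)
    spacers: list[tuple[int, str]]

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def _mean_pairwise_identity(seqs: Sequence[str]) -> float:
    pairs = [(i, j) for i in range(len(seqs)) for j in range(i + 1, len(seqs))]
    if not pairs:
        return 1.0
    return sum(_identity(seqs[i], seqs[j]) for i, j in pairs) / len(pairs)


def detect_arrays(
    contig: str,
    params: CrisprParams | None = None,
    bin_id: str = "",
    contig_id: str = "",
) -> list[CrisprArray]:
    """Detect CRISPR arrays on one contig.

    Contigs shorter than three minimal repeats return an empty list.
    Overlapping candidates are resolved by keeping the one with more repeats
    (ties: longer span, then smaller start); surviving arrays are reported in
    coordinate order.
    """
    p = params or CrisprParams()
    n = len(contig)
    if n < p.min_repeat_length * p.min_repeats:
        return []

    # index seed words -> sorted positions
    seed_pos: dict[str, list[int]] = defaultdict(list)
    L = p.seed_length
    for i in range(n - L + 1):
        word = contig[i : i + L]
        if "N" not in word and "n" not in word:
            seed_pos[word].append(i)

    candidates: list[CrisprArray] = []
    seen_chains: set[tuple[int, ...]] = set()
    for i in range(n - L + 1):
        word = contig[i : i + L]
        occ = seed_pos.get(word)
        if occ is None or len(occ) < p.min_repeats:
            continue
        chain = _chain(occ, i, p)
        if len(chain) < p.min_repeats:
            continue
        key = tuple(chain)
        if key in seen_chains:
            continue
        seen_chains.add(key)
        arr = _build_array(contig, chain, p, bin_id, contig_id)
        if arr is not None:
            candidates.append(arr)

    return _resolve_overlaps(candidates)


def _chain(occ: list[int], start: int, p: CrisprParams) -> list[int]:
    """Greedy chain of seed occurrences at period-compatible spacings."""
    chain = [start]
    cur = start
    while True:
        lo = bisect.bisect_left(occ, cur + p.min_period)
        if lo >= len(occ) or occ[lo] > cur + p.max_period:
            break
        cur = occ[lo]
        chain.append(cur)
    return chain


def _build_array(contig, chain, p: CrisprParams, bin_id, contig_id):
    left, right = _extend(contig, chain, p)
    left, right = _trim_boundaries(contig, chain, left, right, p)
    rep_len = p.seed_length + left + right
    if not (p.min_repeat_length <= rep_len <= p.max_repeat_length):
        return None
    starts = [c - left for c in chain]
    if starts[0] < 0 or starts[-1] + rep_len > len(contig):
        return None

    # trim to the longest run of consecutive repeats with valid spacer gaps
    best_run, run = [starts[0]], [starts[0]]
    for a, b in zip(starts, starts[1:]):
        gap = b - (a + rep_len)
        if p.min_spacer_length <= gap <= p.max_spacer_length:
            run.append(b)
        else:
            run = [b]
        if len(run) > len(best_run):
            best_run = list(run)
    starts = best_run
    if len(starts) < p.min_repeats:
        return None

    repeats = [(s, contig[s : s + rep_len]) for s in starts]
    spacers = [
        (a + rep_len, contig[a + rep_len : b]) for a, b in zip(starts, starts[1:])
    ]
    rep_seqs = [r[1] for r in repeats]
    if _mean_pairwise_identity(rep_seqs) < p.min_repeat_identity:
        return None
    if _mean_pairwise_identity([s[1] for s in spacers]) > p.max_spacer_identity:
        return None
    consensus = "".join(
        Counter(col).most_common(1)[0][0] for col in zip(*rep_seqs)
    )
    return CrisprArray(
        bin_id=bin_id,
        contig_id=contig_id,
        start=starts[0],
        end=starts[-1] + rep_len,
        repeat_consensus=consensus,
        repeats=repeats,
        spacers=spacers,
    )


def _extend(contig, chain, p: CrisprParams) -> tuple[int, int]:
    """Extend seed occurrences outward while columns agree.

    A column is accepted while at least ``extension_agreement`` of the
    instances share the majority base; extension also stops at contig bounds
    and at the maximum repeat length.
    """
    n = len(contig)
    k = len(chain)

    def column_ok(offset: int) -> bool:
        bases = []
        for c in chain:
            j = c + offset
            if j < 0 or j >= n:
                return False
            bases.append(contig[j])
        top = Counter(bases).most_common(1)[0][1]
        return top / k >= p.extension_agreement

    left = 0
    while (
        p.seed_length + left < p.max_repeat_length and column_ok(-(left + 1))
    ):
        left += 1
    right = 0
    while (
        p.seed_length + left + right < p.max_repeat_length
        and column_ok(p.seed_length + right)
    ):
        right += 1
    return left, right


def _trim_boundaries(contig, chain, left, right, p: CrisprParams):
    """Trim extended boundary columns back to unanimity.

    Majority extension can overshoot by a column when flanking bases agree by
    chance; trimming non-unanimous outer columns restores exact repeat
    boundaries on unmutated arrays. The exact-match seed columns are always
    unanimous, so trimming never eats into the seed. Trimming stops at the
    minimum repeat length to preserve sensitivity on mutated arrays.
    """
    n = len(contig)

    def unanimous(offset: int) -> bool:
        bases = set()
        for c in chain:
            j = c + offset
            if j < 0 or j >= n:
                return False
            bases.add(contig[j])
        return len(bases) == 1

    while left > 0 and p.seed_length + left + right > p.min_repeat_length and not unanimous(-left):
        left -= 1
    while right > 0 and p.seed_length + left + right > p.min_repeat_length and not unanimous(
        p.seed_length + right - 1
    ):
        right -= 1
    return left, right


def _resolve_overlaps(candidates: list[CrisprArray]) -> list[CrisprArray]:
    order = sorted(
        candidates, key=lambda a: (-a.n_repeats, -(a.end - a.start), a.start)
    )
    kept: list[CrisprArray] = []
    for arr in order:
        if all(arr.end <= k.start or arr.start >= k.end for k in kept):
            kept.append(arr)
    kept.sort(key=lambda a: a.start)
    return kept


def detect_bin_arrays(
    bin_id: str,
    contigs: dict[str, str],
    params: CrisprParams | None = None,
) -> list[CrisprArray]:
    """Per-contig detection over a whole bin (contigs are not concatenated)."""
    out = []
    for contig_id, seq in contigs.items():
        out.extend(detect_arrays(seq, params, bin_id=bin_id, contig_id=contig_id))
    return out


def extract_spacers(arrays: Iterable[CrisprArray]) -> pd.DataFrame:
    """One row per spacer; duplicate sequences are retained (provenance)."""
    rows = []
    for ai, arr in enumerate(arrays):
        for si, (start, seq) in enumerate(arr.spacers):
            rows.append(
                {
                    "bin_id": arr.bin_id,
                    "contig_id": arr.contig_id,
                    "array_index": ai,
                    "spacer_index": si,
                    "start": start,
                    "sequence": seq,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["bin_id", "contig_id", "array_index", "spacer_index", "start", "sequence"],
    )


def arrays_to_gff3(arrays: Iterable[CrisprArray]) -> str:
    """GFF3 export: one repeat_region per array with direct_repeat children."""
    lines = ["##gff-version 3"]
    for ai, arr in enumerate(arrays):
        aid = f"crispr_{arr.bin_id}_{arr.contig_id}_{ai}"
        lines.append(
            "\t".join(
                [
                    arr.contig_id,
                    "mecphage",
                    "repeat_region",
                    str(arr.start + 1),
                    str(arr.end),
                    ".",
                    ".",
                    ".",
                    f"ID={aid};rpt_family=CRISPR;bin={arr.bin_id}",
                ]
            )
        )
        for ri, (rstart, rseq) in enumerate(arr.repeats):
            lines.append(
                "\t".join(
                    [
                        arr.contig_id,
                        "mecphage",
                        "direct_repeat",
                        str(rstart + 1),
                        str(rstart + len(rseq)),
                        ".",
                        ".",
                        ".",
                        f"ID={aid}_r{ri};Parent={aid}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"
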