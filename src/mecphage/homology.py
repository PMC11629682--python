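"""K-mer sketch ANI, prophage-region calling, induction and spacer matching.

Sketch-based ANI follows the Mash construction: canonical k-mers (lexicographic
minimum of the forward k-mer and its reverse complement under A<C<G<T) are
hashed with a fixed 64-bit finalizer (splitmix64) and the smallest
``sketch_size`` hashes retained. The Jaccard index of two sketches is
estimated from the bottom-``s`` sketch of their union and converted to ANI via

    ANI = 100 * (1 + (1/k) * ln(2J / (1 + J)))

clipped to [0, 100], with J = 0 mapped to ANI 0 by convention.

Prophage regions are called by windowed k-mer containment of each candidate
phage against each bin contig; induction is a sketch-ANI + containment match
of a prophage region against VLP contigs; spacer matching is a full-length
two-strand scan allowing a bounded number of substitutions (no indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from mecphage.errors import IncompatibleSketchesError, TooShortError
from mecphage.seqs import revcomp, seq_to_codes

DEFAULT_K = 17
DEFAULT_SKETCH_SIZE = 1000


# ---------------------------------------------------------------------------
# canonical k-mers and hashing


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer (the documented fixed hash)."""
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x += np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
    return x


def canonical_kmers(seq: str, k: int = DEFAULT_K) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, canonical k-mer codes) for all N-free windows.

    Positions are 0-based starts on the forward strand. k-mers containing
    ambiguous bases are skipped entirely.
    """
    if len(seq) < k:
        raise TooShortError(f"sequence length {len(seq)} < k={k}")
    codes = seq_to_codes(seq)
    win = sliding_window_view(codes, k)
    valid = (win != 255).all(axis=1)
    w = win.astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = (w * powers).sum(axis=1, dtype=np.uint64)
    rc = ((np.uint64(3) - w) * powers[::-1]).sum(axis=1, dtype=np.uint64)
    canon = np.minimum(fwd, rc)
    positions = np.flatnonzero(valid)
    return positions, canon[valid]


def kmer_set(seq: str, k: int = DEFAULT_K) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a sequence."""
    _, kmers = canonical_kmers(seq, k)
    return np.unique(kmers)


def containment(query: np.ndarray, target_sorted: np.ndarray) -> float:
    """Fraction of ``query`` k-mers present in a sorted target array."""
    if query.size == 0:
        return 0.0
    return _membership(query, target_sorted).mean()


def _membership(values: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    if sorted_ref.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_ref, values)
    idx[idx == sorted_ref.size] = sorted_ref.size - 1
    return sorted_ref[idx] == values


# ---------------------------------------------------------------------------
# sketches and ANI


@dataclass(frozen=True)
class KmerSketch:
    source_id: str
    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted ascending, <= sketch_size entries

    def __post_init__(self):
        if self.k < 11:
            raise ValueError("k must be >= 11")


@dataclass(frozen=True)
class AniEstimate:
    id_a: str
    id_b: str
    ani: float  # percent
    jaccard: float
    shared_hashes: int


def sketch(
    seq: str,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    source_id: str = "",
) -> KmerSketch:
    """Bottom-s MinHash sketch of the canonical k-mer set of ``seq``."""
    hashes = np.unique(splitmix64(kmer_set(seq, k)))
    return KmerSketch(source_id, k, sketch_size, hashes[:sketch_size])


def estimate_ani(a: KmerSketch, b: KmerSketch) -> AniEstimate:
    """Mash-style ANI from the bottom-s sketch of the merged hash sets."""
    if a.k != b.k or a.sketch_size != b.sketch_size:
        raise IncompatibleSketchesError(
            f"sketches incompatible: k={a.k}/{b.k}, s={a.sketch_size}/{b.sketch_size}"
        )
    union = np.union1d(a.hashes, b.hashes)
    s = min(a.sketch_size, union.size)
    merged = union[:s]
    shared = int(
        (_membership(merged, a.hashes) & _membership(merged, b.hashes)).sum()
    )
    j = shared / s if s else 0.0
    if j <= 0:
        ani = 0.0
    else:
        ani = float(np.clip(100.0 * (1.0 + np.log(2 * j / (1 + j)) / a.k), 0.0, 100.0))
    return AniEstimate(a.source_id, b.source_id, ani, j, shared)


# ---------------------------------------------------------------------------
# prophage-region calling


@dataclass
class ProphageRegion:
    bin_id: str
    contig_id: str
    start: int  # 0-based half-open on the bin contig
    end: int
    phage_species_id: str
    containment: float
    mean_identity: float  # percent, per-base estimate from containment


@dataclass
class HomologyParams:
    k: int = DEFAULT_K
    window: int = 1000
    step: int = 500
    min_containment: float = 0.5
    min_region_length: int = 5000  # mirrors the >= 5 kb phage length filter
    boundary_window: int = 200
    boundary_density: float = 0.5


class PhageIndex:
    """Combined sorted k-mer index over a set of phage sequences.

    Assumes the phage set is dereplicated (a k-mer shared by two phages is
    attributed to the first one by input order).
    """

    def __init__(self, phages: Mapping[str, str], k: int = DEFAULT_K):
        self.k = k
        self.names = list(phages)
        kmer_arrays = [kmer_set(s, k) for s in phages.values()]
        self.kmer_counts = np.array([a.size for a in kmer_arrays])
        if kmer_arrays:
            allk = np.concatenate(kmer_arrays)
            owners = np.repeat(np.arange(len(kmer_arrays)), self.kmer_counts)
            order = np.argsort(allk, kind="stable")
            allk, owners = allk[order], owners[order]
            keep = np.ones(allk.size, dtype=bool)
            keep[1:] = allk[1:] != allk[:-1]
            self.kmers, self.owners = allk[keep], owners[keep]
        else:
            self.kmers = np.empty(0, dtype=np.uint64)
            self.owners = np.empty(0, dtype=np.int64)

    def match(self, kmers: np.ndarray) -> np.ndarray:
        """Owner index per k-mer, -1 where not present in any phage."""
        out = np.full(kmers.size, -1, dtype=np.int64)
        if self.kmers.size:
            hit = _membership(kmers, self.kmers)
            idx = np.searchsorted(self.kmers, kmers[hit])
            out[hit] = self.owners[idx]
        return out


def detect_prophage_regions(
    bin_id: str,
    contigs: Mapping[str, str],
    phages: Mapping[str, str],
    params: HomologyParams | None = None,
) -> list[ProphageRegion]:
    """Call prophage regions in bin contigs by k-mer containment.

    For every (contig, phage) pair, windows (size/step from ``params``) with
    k-mer containment >= ``min_containment`` seed candidate spans which are
    merged, boundary-refined to the outermost locally dense match positions,
    and reported if at least ``min_region_length`` bp long.
    """
    if not phages:
        raise ValueError("phage set must be non-empty")
    p = params or HomologyParams()
    index = PhageIndex(phages, p.k)
    regions: list[ProphageRegion] = []
    for contig_id, seq in contigs.items():
        if len(seq) < p.k:
            continue
        pos, kmers = canonical_kmers(seq, p.k)
        owner = index.match(kmers)
        for pi in np.unique(owner[owner >= 0]):
            mpos = pos[owner == pi]
            spans = _candidate_spans(mpos, len(seq), p)
            for start, end in spans:
                start, end = _refine(mpos, start, end, p)
                if end - start < p.min_region_length:
                    continue
                n_in = int(((mpos >= start) & (mpos < end)).sum())
                c = min(1.0, n_in / max(1, index.kmer_counts[pi]))
                if c < p.min_containment:
                    continue
                regions.append(
                    ProphageRegion(
                        bin_id=bin_id,
                        contig_id=contig_id,
                        start=int(start),
                        end=int(end),
                        phage_species_id=index.names[pi],
                        containment=float(c),
                        mean_identity=float(100.0 * c ** (1.0 / p.k)),
                    )
                )
    regions.sort(key=lambda r: (r.contig_id, r.start, r.phage_species_id))
    return regions


def _candidate_spans(mpos: np.ndarray, contig_len: int, p: HomologyParams):
    """Merged spans of windows whose match density passes min_containment."""
    if mpos.size == 0:
        return []
    starts = np.arange(0, max(1, contig_len - p.window + 1), p.step)
    counts = np.searchsorted(mpos, starts + p.window) - np.searchsorted(mpos, starts)
    denom = max(1, p.window - p.k + 1)
    ok = counts / denom >= p.min_containment
    spans = []
    for i in np.flatnonzero(ok):
        s, e = int(starts[i]), int(starts[i] + p.window)
        if spans and s <= spans[-1][1]:
            spans[-1][1] = e
        else:
            spans.append([s, e])
    return [(s, e) for s, e in spans]


def _refine(mpos: np.ndarray, start: int, end: int, p: HomologyParams):
    """Extend span to the outermost match positions that sit in a dense
    local neighborhood (filters isolated background hits)."""
    w, dens = p.boundary_window, p.boundary_density
    near = mpos[(mpos >= start - 2 * p.window) & (mpos <= end + 2 * p.window)]
    if near.size == 0:
        return start, end
    fwd = np.searchsorted(near, near + w) - np.arange(near.size)
    bwd = np.arange(near.size) - np.searchsorted(near, near - w) + 1
    need = dens * max(1, w - p.k + 1)
    good = (fwd >= need) | (bwd >= need)
    if not good.any():
        return start, end
    gi = np.flatnonzero(good)
    return int(near[gi[0]]), int(near[gi[-1]] + p.k)


# ---------------------------------------------------------------------------
# induction matching


@dataclass(frozen=True)
class InductionMatch:
    vlp_contig_id: str
    ani: float
    containment: float


def coverage_fraction(
    short_seq: str,
    long_kmers_sorted: np.ndarray,
    k: int = DEFAULT_K,
    chunk: int = 200,
    min_chunk_hits: float = 0.1,
) -> float:
    """Fraction of ``short_seq`` covered by the other sequence's k-mers.

    The sequence is cut into ``chunk``-bp pieces; a piece counts as covered
    when at least ``min_chunk_hits`` of its k-mers occur in the sorted k-mer
    set of the longer sequence. Chunk-level coverage tolerates point
    substitutions (k-mer survival at 95% identity is ~0.42 for k=17, far
    above the 0.1 chunk threshold) while random background stays near zero.
    """
    pos, kmers = canonical_kmers(short_seq, k)
    hit = _membership(kmers, long_kmers_sorted)
    n_chunks = max(1, -(-len(short_seq) // chunk))
    covered = 0
    for ci in range(n_chunks):
        lo, hi = ci * chunk, (ci + 1) * chunk
        sel = (pos >= lo) & (pos < hi)
        n = int(sel.sum())
        if n and hit[sel].mean() >= min_chunk_hits:
            covered += 1
    return covered / n_chunks


def match_induction(
    prophage_seq: str,
    vlp_contigs: Mapping[str, str],
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    min_ani: float = 95.0,
    min_containment: float = 0.8,
) -> list[InductionMatch]:
    """Match a prophage region against VLP contigs.

    A VLP contig matches iff sketch-ANI >= ``min_ani`` and the chunk-level
    coverage of the shorter sequence in the longer is >= ``min_containment``
    (the operationalization of "also detected among the VLP"). Coverage is
    measured per chunk rather than per k-mer so that sequences near the ANI
    threshold still register as contained.
    """
    matches = []
    sk_a = sketch(prophage_seq, k, sketch_size, "prophage")
    km_a = kmer_set(prophage_seq, k)
    for vid, vseq in vlp_contigs.items():
        if len(vseq) < k:
            continue
        ani = estimate_ani(sk_a, sketch(vseq, k, sketch_size, vid)).ani
        if ani < min_ani:
            continue
        if len(prophage_seq) <= len(vseq):
            c = coverage_fraction(prophage_seq, kmer_set(vseq, k), k)
        else:
            c = coverage_fraction(vseq, km_a, k)
        if c >= min_containment:
            matches.append(InductionMatch(vid, ani, float(c)))
    return matches


# ---------------------------------------------------------------------------
# spacer -> protospacer matching


@dataclass(frozen=True)
class SpacerHit:
    bin_id: str
    array_index: int
    spacer_index: int
    spacer_sequence: str
    phage_contig_id: str
    position: int  # 0-based start on the forward strand of the phage contig
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class SpacerQuery:
    bin_id: str
    array_index: int
    spacer_index: int
    sequence: str


def match_spacers(
    spacers: Sequence[SpacerQuery],
    phage_contigs: Mapping[str, str],
    max_mismatches: int = 1,
) -> list[SpacerHit]:
    """Full-length scan of every spacer against both strands of every contig.

    Every placement with <= ``max_mismatches`` substitutions is reported;
    indels are not modeled and ambiguous bases never match.
    """
    hits: list[SpacerHit] = []
    contig_codes = {cid: seq_to_codes(s) for cid, s in phage_contigs.items()}
    for sp in spacers:
        fwd = seq_to_codes(sp.sequence)
        rev = seq_to_codes(revcomp(sp.sequence))
        for cid, codes in contig_codes.items():
            if codes.size < fwd.size:
                continue
            win = sliding_window_view(codes, fwd.size)
            for strand, query in (("+", fwd), ("-", rev)):
                mm = (win != query).sum(axis=1)
                for i in np.flatnonzero(mm <= max_mismatches):
                    hits.append(
                        SpacerHit(
                            sp.bin_id,
                            sp.array_index,
                            sp.spacer_index,
                            sp.sequence,
                            cid,
                            int(i),
                            strand,
                            int(mm[i]),
                        )
                    )
    hits.sort(key=lambda h: (h.bin_id, h.array_index, h.spacer_index, h.phage_contig_id, h.position, h.strand))
    return hits


def ani_table(
    sequences: Mapping[str, str],
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
) -> dict[tuple[str, str], float]:
    """All-vs-all sketch ANI (percent), keyed by unordered id pair."""
    sketches = {
        sid: sketch(s, k, sketch_size, sid) for sid, s in sequences.items() if len(s) >= k
    }
    ids = sorted(sketches)
    table: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            table[(a, b)] = estimate_ani(sketches[a], sketches[b]).ani
    return table
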