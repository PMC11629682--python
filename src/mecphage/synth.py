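"""Ground-truthed synthetic MEC community generator.

Produces prokaryotic genome bins (with planted prophages and CRISPR arrays),
phage contigs (VLP and prokaryotic-dataset), per-contig read counts with
electrode-specific enrichment, a sample manifest, and a ground-truth
manifest, all deterministic for a fixed seed.

Design notes
------------
* Background composition is i.i.d. uniform A/C/G/T so that spurious repeats
  or k-mer collisions are vanishingly unlikely.
* Each species has one "full" genome; its bins differ only by per-base
  substitutions at ``mutation_rate`` plus random contiguous block removal
  down to a target completeness, so true within-species ANI is known.
* Every species (not only electrode-affiliated ones) has a home location in
  which its abundance is multiplied by ``affiliation_effect``; the planted
  electrode-affiliated set is exactly the species homed on an electrode.
* Read counts, not reads, are emitted; mapping is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mecphage.derep import GenomeBin, PhageContig
from mecphage.errors import InfeasibleConfigError
from mecphage.io import SampleRecord
from mecphage.seqs import mutate, random_seq, substream

PROK_LOCATIONS = ("anode", "cathode", "tubing", "suspension")
ALL_LOCATIONS = PROK_LOCATIONS + ("inoculum", "foam")
LIFESTYLE_PREDICTORS = ("phatyp", "vibrant", "phageboost")

_MIN_CONTIG = 3000


def _default_lognormal() -> dict[str, tuple[float, float]]:
    return {loc: (0.0, 1.0) for loc in ALL_LOCATIONS}


@dataclass
class SynthConfig:
    n_mecs: int = 9
    n_host_species: int = 30
    n_phage_species: int = 30
    bins_per_species: tuple[int, int] = (2, 3)
    genome_size_range: tuple[int, int] = (24_000, 40_000)
    contigs_per_genome: tuple[int, int] = (2, 4)
    phage_size_range: tuple[int, int] = (9_000, 15_000)
    prophage_prob: float = 0.6
    induction_prob: float = 0.5
    free_vlp_prob: float = 0.7
    temperate_prob: float = 0.6
    lifestyle_flip_prob: float = 0.1
    crispr_prob: float = 0.6
    spacers_per_array: tuple[int, int] = (3, 6)
    repeat_length_range: tuple[int, int] = (25, 45)
    spacer_length_range: tuple[int, int] = (28, 48)
    protospacer_match_prob: float = 0.7
    mutation_rate: float = 0.002
    completeness_range: tuple[float, float] = (80.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 9.5)
    abundance_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=_default_lognormal
    )
    affiliation_effect: float = 50.0
    anode_fraction: float = 0.2
    cathode_fraction: float = 0.2
    include_inoculum: bool = False
    include_foam: bool = False
    n_decoy_contigs: int = 3
    total_reads_per_sample: int = 100_000
    removal_block_range: tuple[int, int] = (200, 2000)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "prophage_prob": self.prophage_prob,
            "induction_prob": self.induction_prob,
            "free_vlp_prob": self.free_vlp_prob,
            "temperate_prob": self.temperate_prob,
            "lifestyle_flip_prob": self.lifestyle_flip_prob,
            "crispr_prob": self.crispr_prob,
            "protospacer_match_prob": self.protospacer_match_prob,
            "mutation_rate": self.mutation_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise InfeasibleConfigError(f"{name}={p} not in [0,1]")
        lo, hi = self.completeness_range
        if not (0.0 < lo <= hi <= 100.0):
            raise InfeasibleConfigError("completeness_range must be within (0,100]")
        if self.n_mecs < 2:
            raise InfeasibleConfigError("n_mecs must be >= 2 for pairwise statistics")
        if self.bins_per_species[1] > self.n_mecs:
            raise InfeasibleConfigError("more bins per species than MECs to sample from")
        if self.phage_size_range[1] > self.genome_size_range[0]:
            raise InfeasibleConfigError(
                "prophage cannot fit: max phage size exceeds min host genome size"
            )
        if self.genome_size_range[0] < _MIN_CONTIG * self.contigs_per_genome[1]:
            raise InfeasibleConfigError("genomes too small for the contig count range")
        rlo, rhi = self.repeat_length_range
        slo, shi = self.spacer_length_range
        if not (23 <= rlo <= rhi <= 47):
            raise InfeasibleConfigError("repeat lengths must lie in [23,47]")
        if not (26 <= slo <= shi <= 50):
            raise InfeasibleConfigError("spacer lengths must lie in [26,50]")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# truncation


class TruncatedGenome:
    """Result of random block removal from a multi-contig genome.

    Keeps, per contig, the retained original-coordinate segments so planted
    feature intervals can be projected into bin coordinates.
    """

    def __init__(self, contigs: dict[str, str], segments: dict[str, list[tuple[int, int]]]):
        self._source = contigs
        self.segments = segments
        self.contigs: dict[str, str] = {}
        for cid, seq in contigs.items():
            segs = segments[cid]
            if segs:
                self.contigs[cid] = "".join(seq[a:b] for a, b in segs)

    @property
    def retained_length(self) -> int:
        return sum(b - a for segs in self.segments.values() for a, b in segs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._source.values())

    @property
    def retained_fraction(self) -> float:
        return self.retained_length / self.total_length

    def project(self, contig_id: str, start: int, end: int):
        """Project an original-coordinate interval into the bin.

        Returns (retained_bases, n_pieces, bin_start, bin_end, intact) where
        bin coordinates span the outermost retained pieces and ``intact``
        means the whole interval survived as a single piece.
        """
        segs = self.segments.get(contig_id, [])
        retained = 0
        pieces = 0
        bin_start = bin_end = None
        offset = 0
        for a, b in segs:
            lo, hi = max(a, start), min(b, end)
            if lo < hi:
                pieces += 1
                retained += hi - lo
                if bin_start is None:
                    bin_start = offset + (lo - a)
                bin_end = offset + (hi - a)
            offset += b - a
        intact = pieces == 1 and retained == (end - start)
        return retained, pieces, bin_start, bin_end, intact


def truncate_bin(
    contigs: Mapping[str, str],
    completeness_target: float,
    rng: np.random.Generator | int,
    block_range: tuple[int, int] = (200, 2000),
) -> TruncatedGenome:
    """Remove contiguous random blocks until the retained fraction hits target.

    Blocks are placed uniformly over the currently retained sequence (contig
    chosen proportionally to retained length); prophage and CRISPR regions
    are removable like any other region. The retained fraction lands within
    one point of ``completeness_target``.
    """
    if not 0.0 < completeness_target <= 100.0:
        raise ValueError("completeness_target must be in (0,100]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    segments = {cid: [(0, len(seq))] for cid, seq in contigs.items()}
    total = sum(len(s) for s in contigs.values())
    target = total * completeness_target / 100.0
    retained = total
    while retained > target + 0.5:
        deficit = int(np.ceil(retained - target))
        size = min(deficit, int(rng.integers(block_range[0], block_range[1] + 1)))
        weights = np.array(
            [sum(b - a for a, b in segments[cid]) for cid in contigs], dtype=float
        )
        if weights.sum() <= 0:
            break
        cid = list(contigs)[rng.choice(len(weights), p=weights / weights.sum())]
        clen = int(weights[list(contigs).index(cid)])
        off = int(rng.integers(0, max(1, clen)))
        removed = _remove_retained_span(segments[cid], off, size)
        retained -= removed
        if removed == 0:
            break
    return TruncatedGenome(dict(contigs), segments)


def _remove_retained_span(segs: list[tuple[int, int]], offset: int, size: int) -> int:
    """Remove [offset, offset+size) measured in retained coordinates."""
    out: list[tuple[int, int]] = []
    removed = 0
    pos = 0
    for a, b in segs:
        seg_len = b - a
        lo = max(0, offset - pos)
        hi = min(seg_len, offset + size - pos)
        if lo < hi:
            if lo > 0:
                out.append((a, a + lo))
            if hi < seg_len:
                out.append((a + hi, b))
            removed += hi - lo
        else:
            out.append((a, b))
        pos += seg_len
    segs[:] = out
    return removed


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruth:
    prophages: pd.DataFrame  # per (bin, planted prophage) retention record
    induced: pd.DataFrame  # (host_species, phage_species) pairs
    crispr_links: pd.DataFrame
    planted_arrays: pd.DataFrame
    array_bins: pd.DataFrame
    affiliated: pd.DataFrame  # species_id, call
    membership: pd.DataFrame  # member_id, species_id, kind

    def write_tsv(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "prophages",
            "induced",
            "crispr_links",
            "planted_arrays",
            "array_bins",
            "affiliated",
            "membership",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


@dataclass
class SyntheticDataset:
    config: SynthConfig
    samples: list[SampleRecord]
    bins: list[GenomeBin]
    phage_contigs: list[PhageContig]
    counts_prok: pd.DataFrame  # rows "bin|contig", columns prokaryotic samples
    counts_vlp: pd.DataFrame  # rows phage contig ids, columns VLP samples
    truth: GroundTruth


# ---------------------------------------------------------------------------
# generator


def generate_dataset(config: SynthConfig, outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset (optionally writing it to disk)."""
    config.validate()
    seed = config.seed
    rng_phage = substream(seed, "phages")
    rng_genome = substream(seed, "genomes")
    rng_plant = substream(seed, "planting")
    rng_bins = substream(seed, "bins")
    rng_meta = substream(seed, "metadata")
    rng_abund = substream(seed, "abundance")

    samples = _make_samples(config)
    prok_samples = [s for s in samples if s.dataset == "prokaryotic"]
    vlp_samples = [s for s in samples if s.dataset == "VLP"]

    # phage species
    phage_ids = [f"P{i + 1:03d}" for i in range(config.n_phage_species)]
    canon = {
        pid: random_seq(
            rng_phage, int(rng_phage.integers(*_incl(config.phage_size_range)))
        )
        for pid in phage_ids
    }
    true_temperate = {
        pid: bool(rng_phage.random() < config.temperate_prob) for pid in phage_ids
    }
    temperate_pool = [p for p in phage_ids if true_temperate[p]]

    # host species, affiliation homes, prophage assignment
    host_ids = [f"H{i + 1:03d}" for i in range(config.n_host_species)]
    home = _assign_homes(host_ids, config, rng_plant)
    prophage_of: dict[str, str] = {}
    for h in host_ids:
        if rng_plant.random() < config.prophage_prob:
            if not temperate_pool:
                raise InfeasibleConfigError(
                    "prophage_prob > 0 but no temperate phage species were drawn"
                )
            prophage_of[h] = temperate_pool[rng_plant.integers(len(temperate_pool))]

    # VLP membership
    prophage_species = set(prophage_of.values())
    vlp_species = set()
    for pid in phage_ids:
        p = config.induction_prob if pid in prophage_species else config.free_vlp_prob
        if rng_plant.random() < p:
            vlp_species.add(pid)
    vlp_pool = sorted(vlp_species)

    # full genomes with planted features
    genomes: dict[str, dict[str, str]] = {}
    prophage_sites: dict[str, tuple[str, int, int, str]] = {}  # host -> (contig, a, b, pid)
    arrays_rows, spacer_feats = [], {}  # host -> list of spacer feature dicts
    array_sites: dict[str, tuple[str, int, int]] = {}
    for h in host_ids:
        contigs = _make_genome(config, rng_genome)
        if h in prophage_of:
            pid = prophage_of[h]
            cid = _weighted_contig(contigs, rng_plant)
            pos = int(rng_plant.integers(0, len(contigs[cid]) + 1))
            contigs[cid] = contigs[cid][:pos] + canon[pid] + contigs[cid][pos:]
            prophage_sites[h] = (cid, pos, pos + len(canon[pid]), pid)
        if rng_plant.random() < config.crispr_prob:
            arr = _make_array(config, rng_plant, canon, vlp_pool)
            cid, pos = _array_position(contigs, prophage_sites.get(h), rng_plant)
            contigs[cid] = contigs[cid][:pos] + arr["sequence"] + contigs[cid][pos:]
            if h in prophage_sites and prophage_sites[h][0] == cid:
                pcid, pa, pb, ppid = prophage_sites[h]
                if pos <= pa:
                    prophage_sites[h] = (pcid, pa + len(arr["sequence"]), pb + len(arr["sequence"]), ppid)
            array_sites[h] = (cid, pos, pos + len(arr["sequence"]))
            arrays_rows.append(
                {
                    "host_species": h,
                    "array_id": f"{h}_arr1",
                    "contig_id": cid,
                    "start": pos,
                    "end": pos + len(arr["sequence"]),
                    "repeat_consensus": arr["repeat"],
                    "n_spacers": len(arr["spacers"]),
                    "spacers": ",".join(s["sequence"] for s in arr["spacers"]),
                }
            )
            spacer_feats[h] = [
                {
                    "start": pos + s["offset"],
                    "end": pos + s["offset"] + len(s["sequence"]),
                    "sequence": s["sequence"],
                    "phage_species": s["phage_species"],
                }
                for s in arr["spacers"]
            ]
        genomes[h] = contigs

    # bins
    bins: list[GenomeBin] = []
    prophage_rows, array_bin_rows = [], []
    spacer_retained: dict[tuple[str, int], int] = {}
    for h in host_ids:
        n_bins = int(rng_bins.integers(*_incl(config.bins_per_species)))
        mecs = rng_bins.choice(config.n_mecs, size=n_bins, replace=False)
        for bi, mec in enumerate(sorted(int(m) for m in mecs)):
            bin_id = f"{h}_b{bi + 1}"
            sample_id = f"M{mec + 1}_{home[h]}_pro"
            mutated = {}
            for cid, seq in genomes[h].items():
                mseq, _ = mutate(seq, config.mutation_rate, rng_bins)
                mutated[cid] = mseq
            target = float(rng_bins.uniform(*config.completeness_range))
            trunc = truncate_bin(mutated, target, rng_bins, config.removal_block_range)
            completeness = 100.0 * trunc.retained_fraction
            contamination = float(rng_bins.uniform(*config.contamination_range))
            bins.append(
                GenomeBin(
                    bin_id=bin_id,
                    sample_id=sample_id,
                    contigs=trunc.contigs,
                    completeness=completeness,
                    contamination=contamination,
                    taxonomy=f"tax_{h}",
                )
            )
            if h in prophage_sites:
                cid, a, b, pid = prophage_sites[h]
                ret, pieces, bs, be, intact = trunc.project(cid, a, b)
                prophage_rows.append(
                    {
                        "host_species": h,
                        "phage_species": pid,
                        "bin_id": bin_id,
                        "contig_id": cid,
                        "bin_start": -1 if bs is None else bs,
                        "bin_end": -1 if be is None else be,
                        "retained_bases": ret,
                        "retained_fraction": ret / (b - a),
                        "phage_length": b - a,
                        "n_pieces": pieces,
                    }
                )
            if h in array_sites:
                cid, a, b = array_sites[h]
                ret, pieces, bs, be, intact = trunc.project(cid, a, b)
                array_bin_rows.append(
                    {
                        "host_species": h,
                        "array_id": f"{h}_arr1",
                        "bin_id": bin_id,
                        "intact": intact,
                        "retained_bases": ret,
                        "bin_start": -1 if bs is None else bs,
                        "bin_end": -1 if be is None else be,
                    }
                )
                for si, sf in enumerate(spacer_feats[h]):
                    _, _, _, _, s_intact = trunc.project(cid, sf["start"], sf["end"])
                    if s_intact:
                        spacer_retained[(h, si)] = spacer_retained.get((h, si), 0) + 1

    # phage contigs + metadata
    phage_contigs = _make_phage_contigs(
        config, canon, true_temperate, vlp_species, prophage_species, rng_meta
    )

    # read counts
    counts_prok = _prok_counts(config, prok_samples, bins, host_ids, home, rng_abund)
    counts_vlp = _vlp_counts(config, vlp_samples, phage_contigs, rng_abund)

    truth = _build_truth(
        config,
        host_ids,
        home,
        prophage_of,
        prophage_rows,
        vlp_species,
        arrays_rows,
        array_bin_rows,
        spacer_feats,
        spacer_retained,
        bins,
        phage_contigs,
    )

    ds = SyntheticDataset(
        config=config,
        samples=samples,
        bins=bins,
        phage_contigs=phage_contigs,
        counts_prok=counts_prok,
        counts_vlp=counts_vlp,
        truth=truth,
    )
    if outdir is not None:
        from mecphage.io import write_dataset

        write_dataset(ds, Path(outdir))
    return ds


# ---------------------------------------------------------------------------
# helpers


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def _make_samples(config: SynthConfig) -> list[SampleRecord]:
    samples = []
    for m in range(config.n_mecs):
        mec = f"M{m + 1}"
        for loc in PROK_LOCATIONS:
            samples.append(SampleRecord(f"{mec}_{loc}_pro", mec, loc, "prokaryotic"))
    if config.include_inoculum:
        samples.append(SampleRecord("M0_inoculum_pro", "M0", "inoculum", "prokaryotic"))
    if config.include_foam:
        samples.append(SampleRecord("M0_foam_pro", "M0", "foam", "prokaryotic"))
    for m in range(config.n_mecs):
        mec = f"M{m + 1}"
        samples.append(SampleRecord(f"{mec}_liquid_vlp", mec, "suspension", "VLP"))
    return samples


def _assign_homes(host_ids, config: SynthConfig, rng) -> dict[str, str]:
    n = len(host_ids)
    n_anode = int(round(config.anode_fraction * n))
    n_cathode = int(round(config.cathode_fraction * n))
    order = [host_ids[i] for i in rng.permutation(n)]
    home = {}
    for i, h in enumerate(order):
        if i < n_anode:
            home[h] = "anode"
        elif i < n_anode + n_cathode:
            home[h] = "cathode"
        else:
            home[h] = "tubing" if rng.random() < 0.5 else "suspension"
    return home


def _make_genome(config: SynthConfig, rng) -> dict[str, str]:
    total = int(rng.integers(*_incl(config.genome_size_range)))
    n_contigs = int(rng.integers(*_incl(config.contigs_per_genome)))
    # random split with a minimum contig size
    free = total - _MIN_CONTIG * n_contigs
    cuts = np.sort(rng.integers(0, free + 1, size=n_contigs - 1)) if n_contigs > 1 else np.array([], dtype=int)
    parts = np.diff(np.concatenate([[0], cuts, [free]])) + _MIN_CONTIG
    return {f"c{i + 1}": random_seq(rng, int(p)) for i, p in enumerate(parts)}


def _weighted_contig(contigs: dict[str, str], rng) -> str:
    ids = list(contigs)
    w = np.array([len(contigs[c]) for c in ids], dtype=float)
    return ids[rng.choice(len(ids), p=w / w.sum())]


def _make_array(config: SynthConfig, rng, canon, vlp_pool) -> dict:
    rep_len = int(rng.integers(*_incl(config.repeat_length_range)))
    repeat = random_seq(rng, rep_len)
    n_spacers = int(rng.integers(*_incl(config.spacers_per_array)))
    spacers = []
    offset = rep_len
    for _ in range(n_spacers):
        s_len = int(rng.integers(*_incl(config.spacer_length_range)))
        phage_sp = None
        if vlp_pool and rng.random() < config.protospacer_match_prob:
            phage_sp = vlp_pool[rng.integers(len(vlp_pool))]
            src = canon[phage_sp]
            start = int(rng.integers(0, len(src) - s_len + 1))
            seq = src[start : start + s_len]
        else:
            seq = random_seq(rng, s_len)
        spacers.append({"offset": offset, "sequence": seq, "phage_species": phage_sp})
        offset += s_len + rep_len
    sequence = repeat + "".join(s["sequence"] + repeat for s in spacers)
    return {"repeat": repeat, "spacers": spacers, "sequence": sequence}


def _array_position(contigs, prophage_site, rng) -> tuple[str, int]:
    for _ in range(100):
        cid = _weighted_contig(contigs, rng)
        pos = int(rng.integers(0, len(contigs[cid]) + 1))
        if prophage_site is not None and prophage_site[0] == cid:
            _, a, b, _ = prophage_site
            if a < pos < b:
                continue
        return cid, pos
    raise InfeasibleConfigError("could not place CRISPR array outside the prophage")


def _make_phage_contigs(
    config, canon, true_temperate, vlp_species, prophage_species, rng
) -> list[PhageContig]:
    contigs = []
    for pid in sorted(canon):
        emit = []
        if pid in vlp_species:
            emit.append((f"{pid}_v1", "VLP"))
        if pid in prophage_species:
            emit.append((f"{pid}_pro1", "PRO"))
        for cid, dataset in emit:
            seq, _ = mutate(canon[pid], config.mutation_rate, rng)
            label = "temperate" if true_temperate[pid] else "virulent"
            other = "virulent" if label == "temperate" else "temperate"
            lifestyles = {
                pred: (other if rng.random() < config.lifestyle_flip_prob else label)
                for pred in LIFESTYLE_PREDICTORS
            }
            contigs.append(
                PhageContig(
                    contig_id=cid,
                    dataset=dataset,
                    sequence=seq,
                    viral_gene_count=int(rng.integers(1, 21)),
                    lifestyles=lifestyles,
                    completeness=float(rng.uniform(50.0, 100.0)),
                )
            )
    # decoys exercising the length / viral-gene filters
    patterns = [(3000, 2), (8000, 0), (2000, 0)]
    for i in range(config.n_decoy_contigs):
        length, genes = patterns[i % len(patterns)]
        contigs.append(
            PhageContig(
                contig_id=f"junk{i + 1}",
                dataset="VLP" if i % 2 == 0 else "PRO",
                sequence=random_seq(rng, length),
                viral_gene_count=genes,
                lifestyles={p: "virulent" for p in LIFESTYLE_PREDICTORS},
                completeness=float(rng.uniform(10.0, 50.0)),
            )
        )
    return contigs


def _prok_counts(config, prok_samples, bins, host_ids, home, rng) -> pd.DataFrame:
    contig_rows = []
    contig_host = []
    contig_len = []
    for b in bins:
        h = b.bin_id.rsplit("_b", 1)[0]
        for cid, seq in b.contigs.items():
            contig_rows.append(f"{b.bin_id}|{cid}")
            contig_host.append(h)
            contig_len.append(len(seq))
    contig_host = np.array(contig_host)
    contig_len = np.array(contig_len, dtype=float)
    host_len = {h: contig_len[contig_host == h].sum() for h in host_ids}

    data = {}
    for s in prok_samples:
        mu, sigma = config.abundance_lognormal.get(s.location, (0.0, 1.0))
        w = {h: float(rng.lognormal(mu, sigma)) for h in host_ids}
        for h in host_ids:
            if home[h] == s.location:
                w[h] *= config.affiliation_effect
        total_w = sum(w.values())
        col = np.zeros(len(contig_rows))
        for i, (h, L) in enumerate(zip(contig_host, contig_len)):
            col[i] = config.total_reads_per_sample * (w[h] / total_w) * (L / host_len[h])
        data[s.sample_id] = np.round(col).astype(int)
    df = pd.DataFrame(data, index=contig_rows)
    df.index.name = "contig"
    return df.sort_index()


def _vlp_counts(config, vlp_samples, phage_contigs, rng) -> pd.DataFrame:
    vlp_ids = [c.contig_id for c in phage_contigs if c.dataset == "VLP"]
    mu, sigma = config.abundance_lognormal.get("suspension", (0.0, 1.0))
    data = {}
    for s in vlp_samples:
        if not vlp_ids:
            data[s.sample_id] = np.empty(0, dtype=int)
            continue
        w = np.array([rng.lognormal(mu, sigma) for _ in vlp_ids])
        col = config.total_reads_per_sample * w / w.sum()
        data[s.sample_id] = np.round(col).astype(int)
    df = pd.DataFrame(data, index=vlp_ids)
    df.index.name = "contig"
    return df.sort_index()


def _build_truth(
    config,
    host_ids,
    home,
    prophage_of,
    prophage_rows,
    vlp_species,
    arrays_rows,
    array_bin_rows,
    spacer_feats,
    spacer_retained,
    bins,
    phage_contigs,
) -> GroundTruth:
    prophages = pd.DataFrame(
        prophage_rows,
        columns=[
            "host_species",
            "phage_species",
            "bin_id",
            "contig_id",
            "bin_start",
            "bin_end",
            "retained_bases",
            "retained_fraction",
            "phage_length",
            "n_pieces",
        ],
    )
    induced = pd.DataFrame(
        [
            {"host_species": h, "phage_species": p}
            for h, p in sorted(prophage_of.items())
            if p in vlp_species
        ],
        columns=["host_species", "phage_species"],
    )

    link_rows = []
    intact_by_array = {}
    for row in array_bin_rows:
        key = row["host_species"]
        intact_by_array[key] = intact_by_array.get(key, 0) + (1 if row["intact"] else 0)
    for h, feats in spacer_feats.items():
        for si, sf in enumerate(feats):
            if sf["phage_species"] is None:
                continue
            link_rows.append(
                {
                    "host_species": h,
                    "phage_species": sf["phage_species"],
                    "spacer_sequence": sf["sequence"],
                    "spacer_index": si,
                    "mismatches": 0,
                    "spacer_retained_bins": spacer_retained.get((h, si), 0),
                    "array_intact_bins": intact_by_array.get(h, 0),
                }
            )
    crispr_links = pd.DataFrame(
        link_rows,
        columns=[
            "host_species",
            "phage_species",
            "spacer_sequence",
            "spacer_index",
            "mismatches",
            "spacer_retained_bins",
            "array_intact_bins",
        ],
    )

    affiliated = pd.DataFrame(
        [
            {
                "species_id": h,
                "call": home[h] if home[h] in ("anode", "cathode") else "none",
            }
            for h in host_ids
        ]
    )

    member_rows = [
        {"member_id": b.bin_id, "species_id": b.bin_id.rsplit("_b", 1)[0], "kind": "prokaryote"}
        for b in bins
    ]
    for c in phage_contigs:
        if c.contig_id.startswith("junk"):
            continue
        member_rows.append(
            {
                "member_id": c.contig_id,
                "species_id": c.contig_id.rsplit("_", 1)[0],
                "kind": "phage",
            }
        )
    membership = pd.DataFrame(member_rows, columns=["member_id", "species_id", "kind"])

    return GroundTruth(
        prophages=prophages,
        induced=induced,
        crispr_links=crispr_links,
        planted_arrays=pd.DataFrame(
            arrays_rows,
            columns=[
                "host_species",
                "array_id",
                "contig_id",
                "start",
                "end",
                "repeat_consensus",
                "n_spacers",
                "spacers",
            ],
        ),
        array_bins=pd.DataFrame(
            array_bin_rows,
            columns=[
                "host_species",
                "array_id",
                "bin_id",
                "intact",
                "retained_bases",
                "bin_start",
                "bin_end",
            ],
        ),
        affiliated=affiliated,
        membership=membership,
    )
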