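"""Quality filtering and 95%-ANI species clustering with representatives.

Clustering is average-linkage hierarchical clustering on d = 1 - ANI/100 cut
at d = 0.05 (the conventional 95% species boundary), with deterministic
species ids derived from the lexicographically smallest member. Prokaryote
representatives maximize completeness - 5*contamination + 0.5*log10(N50);
phage representatives maximize completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class GenomeBin:
    bin_id: str
    sample_id: str
    contigs: dict[str, str]
    completeness: float
    contamination: float
    taxonomy: str | None = None

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def n50(self) -> int:
        return n50([len(s) for s in self.contigs.values()])


@dataclass
class PhageContig:
    contig_id: str
    dataset: str  # "VLP" or "PRO"
    sequence: str
    viral_gene_count: int
    lifestyles: dict[str, str] = field(default_factory=dict)  # predictor -> label
    completeness: float = 0.0

    @property
    def lifestyle(self) -> str:
        """Consensus label; 'ambiguous' when predictors disagree or are absent."""
        labels = {v for v in self.lifestyles.values() if v in ("temperate", "virulent")}
        if len(labels) == 1:
            return labels.pop()
        return "ambiguous"

    @property
    def temperate_by_any(self) -> bool:
        return any(v == "temperate" for v in self.lifestyles.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SpeciesCluster:
    species_id: str
    kind: str  # "prokaryote" or "phage"
    member_ids: list[str]
    representative_id: str | None = None


def n50(lengths: Sequence[int]) -> int:
    if not lengths:
        return 0
    lens = sorted(lengths, reverse=True)
    half = sum(lens) / 2
    acc = 0
    for L in lens:
        acc += L
        if acc >= half:
            return L
    return lens[-1]


def filter_phage_contigs(
    contigs: Iterable[PhageContig],
    min_length: int = 5000,
    min_viral_genes: int = 1,
) -> list[PhageContig]:
    """Keep contigs >= 5 kb with at least one viral gene; order preserved."""
    return [
        c
        for c in contigs
        if len(c) >= min_length and c.viral_gene_count >= min_viral_genes
    ]


def cluster_species(
    item_ids: Sequence[str],
    ani: Mapping[tuple[str, str], float],
    threshold: float = 95.0,
    kind: str = "prokaryote",
    id_prefix: str | None = None,
) -> list[SpeciesCluster]:
    """Average-linkage clustering of items at the given ANI threshold.

    ``ani`` maps unordered id pairs to percent identity; absent pairs are
    treated as ANI 0. Memberships are invariant to input order (items are
    sorted internally, so ids only depend on the set of members).
    """
    ids = sorted(item_ids)
    prefix = id_prefix if id_prefix is not None else ("S" if kind == "prokaryote" else "vS")
    if not ids:
        return []
    if len(ids) == 1:
        return [SpeciesCluster(f"{prefix}001", kind, [ids[0]])]

    def get(a: str, b: str) -> float:
        return ani.get((a, b), ani.get((b, a), 0.0))

    n = len(ids)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - get(ids[i], ids[j]) / 100.0
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=1.0 - threshold / 100.0, criterion="distance")

    groups: dict[int, list[str]] = {}
    for lab, item in zip(labels, ids):
        groups.setdefault(int(lab), []).append(item)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    return [
        SpeciesCluster(f"{prefix}{i + 1:03d}", kind, sorted(members))
        for i, members in enumerate(ordered)
    ]


def select_representative(
    cluster: SpeciesCluster,
    metadata: Mapping[str, GenomeBin] | Mapping[str, PhageContig],
) -> str:
    """Pick the cluster representative.

    Prokaryotes score completeness - 5*contamination + 0.5*log10(N50);
    phages use completeness alone. Ties break by total length, then id.
    """
    if not cluster.member_ids:
        raise ValueError("cluster is empty")

    def key(member_id: str):
        m = metadata[member_id]
        if isinstance(m, GenomeBin):
            score = (
                m.completeness
                - 5.0 * m.contamination
                + 0.5 * math.log10(max(m.n50, 1))
            )
            length = m.total_length
        else:
            score = m.completeness
            length = len(m)
        # sort descending on score and length, ascending on id
        return (-score, -length, member_id)

    return min(cluster.member_ids, key=key)


def assign_representatives(clusters, metadata) -> None:
    for c in clusters:
        c.representative_id = select_representative(c, metadata)


def retain_prokaryote_species(
    clusters: Iterable[SpeciesCluster],
    metadata: Mapping[str, GenomeBin],
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
) -> list[SpeciesCluster]:
    """Keep clusters with a member of >70% completeness and <10% contamination
    (strict inequalities as printed)."""
    kept = []
    for c in clusters:
        for m in c.member_ids:
            b = metadata[m]
            if b.completeness > min_completeness and b.contamination < max_contamination:
                kept.append(c)
                break
    return kept


def membership_table(clusters: Iterable[SpeciesCluster]) -> pd.DataFrame:
    rows = [
        {
            "member_id": m,
            "species_id": c.species_id,
            "is_representative": m == c.representative_id,
        }
        for c in clusters
        for m in c.member_ids
    ]
    return pd.DataFrame(rows, columns=["member_id", "species_id", "is_representative"])


def membership_map(clusters: Iterable[SpeciesCluster]) -> dict[str, str]:
    return {m: c.species_id for c in clusters for m in c.member_ids}
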