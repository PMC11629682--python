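"""Host-phage association network construction and abundance summaries.

Evidence classes: ``prophage`` (temperate phage region inside a member bin),
``induced_prophage`` (that region also matched among VLP contigs) and
``crispr_match`` (spacer-protospacer hit). An ``induced_prophage`` record can
only exist alongside a ``prophage`` record for the same (host, phage) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from mecphage.errors import DanglingReferenceError
from mecphage.homology import ProphageRegion, SpacerHit

logger = logging.getLogger(__name__)

EVIDENCE_TYPES = ("prophage", "induced_prophage", "crispr_match")


@dataclass
class Association:
    host_species_id: str
    phage_species_id: str
    evidence: str
    records: list[str] = field(default_factory=list)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.host_species_id, self.phage_species_id)


def _region_key(r: ProphageRegion) -> str:
    return f"{r.bin_id}:{r.contig_id}:{r.start}-{r.end}:{r.phage_species_id}"


def call_prophage_associations(
    regions: Sequence[ProphageRegion],
    temperate_by_any: Mapping[str, bool],
    bin_to_host: Mapping[str, str],
) -> tuple[list[Association], list[str]]:
    """Species-level prophage edges from per-bin regions.

    A region yields an edge iff the phage species is temperate under at least
    one lifestyle predictor (logical OR); regions virulent by all predictors
    are excluded and returned in the skip log. Multiple bins of one host
    species carrying the same phage species collapse to one edge with
    multiple supporting records.
    """
    edges: dict[tuple[str, str], Association] = {}
    skipped: list[str] = []
    for r in regions:
        if r.bin_id not in bin_to_host:
            raise DanglingReferenceError(f"region references unknown bin {r.bin_id!r}")
        if r.phage_species_id not in temperate_by_any:
            raise DanglingReferenceError(
                f"region references unknown phage species {r.phage_species_id!r}"
            )
        if not temperate_by_any[r.phage_species_id]:
            skipped.append(_region_key(r))
            logger.info("excluding virulent-by-all region %s", _region_key(r))
            continue
        pair = (bin_to_host[r.bin_id], r.phage_species_id)
        if pair not in edges:
            edges[pair] = Association(*pair, "prophage")
        edges[pair].records.append(_region_key(r))
    return list(edges.values()), skipped


def promote_induced(
    associations: Sequence[Association],
    induction_matches: Mapping[str, Sequence[str]],
) -> tuple[list[Association], list[str]]:
    """Add induced_prophage evidence to prophage edges with VLP matches.

    ``induction_matches`` maps a region record key to the VLP contig ids it
    matched. Matches whose region key belongs to no prophage edge are
    returned as orphans (no new edge is created).
    """
    out = list(associations)
    known_keys = {
        rec: a for a in associations if a.evidence == "prophage" for rec in a.records
    }
    induced: dict[tuple[str, str], Association] = {}
    orphans: list[str] = []
    for key, vlp_ids in induction_matches.items():
        if not vlp_ids:
            continue
        base = known_keys.get(key)
        if base is None:
            orphans.append(key)
            logger.info("induction match without prophage edge: %s", key)
            continue
        edge = induced.setdefault(
            base.pair, Association(*base.pair, "induced_prophage")
        )
        edge.records.extend(f"{key}~{v}" for v in vlp_ids)
    out.extend(induced.values())
    return out, orphans


def call_crispr_associations(
    hits: Sequence[SpacerHit],
    bin_to_host: Mapping[str, str],
    contig_to_phage_species: Mapping[str, str],
    vlp_contig_ids: set[str] | None = None,
) -> list[Association]:
    """Species-level crispr_match edges from spacer hits.

    When ``vlp_contig_ids`` is given, only hits against those contigs are
    used (the default pipeline behavior, matching associations "with phages
    found among the VLP").
    """
    edges: dict[tuple[str, str], Association] = {}
    for h in hits:
        if h.bin_id not in bin_to_host:
            raise DanglingReferenceError(f"hit references unknown bin {h.bin_id!r}")
        if h.phage_contig_id not in contig_to_phage_species:
            raise DanglingReferenceError(
                f"hit references unknown phage contig {h.phage_contig_id!r}"
            )
        if vlp_contig_ids is not None and h.phage_contig_id not in vlp_contig_ids:
            continue
        pair = (bin_to_host[h.bin_id], contig_to_phage_species[h.phage_contig_id])
        if pair not in edges:
            edges[pair] = Association(*pair, "crispr_match")
        edges[pair].records.append(
            f"{h.bin_id}:a{h.array_index}:s{h.spacer_index}->{h.phage_contig_id}@{h.position}{h.strand}"
        )
    return list(edges.values())


def build_network(
    associations: Sequence[Association],
    host_labels: Mapping[str, str] | None = None,
    phage_labels: Mapping[str, str] | None = None,
) -> nx.MultiGraph:
    """Bipartite multigraph; one edge per (host, phage, evidence) triple."""
    g = nx.MultiGraph()
    for a in associations:
        if not g.has_node(a.host_species_id):
            g.add_node(
                a.host_species_id,
                kind="host",
                taxonomy=(host_labels or {}).get(a.host_species_id, ""),
            )
        if not g.has_node(a.phage_species_id):
            g.add_node(
                a.phage_species_id,
                kind="phage",
                lifestyle=(phage_labels or {}).get(a.phage_species_id, ""),
            )
        g.add_edge(
            a.host_species_id,
            a.phage_species_id,
            key=a.evidence,
            evidence=a.evidence,
            n_support=len(a.records),
            records=";".join(a.records),
        )
    return g


def edge_table(associations: Sequence[Association]) -> pd.DataFrame:
    rows = [
        {
            "host_species": a.host_species_id,
            "phage_species": a.phage_species_id,
            "evidence": a.evidence,
            "n_support": len(a.records),
            "records": ";".join(a.records),
        }
        for a in associations
    ]
    df = pd.DataFrame(
        rows, columns=["host_species", "phage_species", "evidence", "n_support", "records"]
    )
    return df.sort_values(["host_species", "phage_species", "evidence"]).reset_index(
        drop=True
    )


def associations_from_table(df: pd.DataFrame) -> list[Association]:
    """Inverse of ``edge_table`` (lossless round-trip)."""
    out = []
    for _, row in df.iterrows():
        records = str(row["records"]).split(";") if row["records"] else []
        out.append(
            Association(
                row["host_species"], row["phage_species"], row["evidence"], records
            )
        )
    return out


def summarize_network_abundance(
    associations: Sequence[Association],
    phage_abundance: pd.DataFrame,  # phage species x VLP samples, percent
    affiliation: Mapping[str, str],  # host species -> anode|cathode|none
) -> pd.DataFrame:
    """Per-sample summed abundance of phages by host-affiliation category.

    Categories: anode-affiliated hosts, cathode-affiliated hosts,
    non-electrode hosts, and phages with no associated host. A phage
    associated with hosts in several categories counts in each (overlap is
    allowed by design).
    """
    if phage_abundance.shape[1] == 0:
        return pd.DataFrame(
            columns=["category", "n_phage_species", "min_percent", "max_percent"]
        )
    assoc_by_phage: dict[str, set[str]] = {}
    for a in associations:
        assoc_by_phage.setdefault(a.phage_species_id, set()).add(a.host_species_id)

    cats = {"anode": set(), "cathode": set(), "non_electrode": set(), "unassociated": set()}
    for phage in phage_abundance.index:
        hosts = assoc_by_phage.get(phage, set())
        if not hosts:
            cats["unassociated"].add(phage)
            continue
        for h in hosts:
            call = affiliation.get(h, "none")
            cats["anode" if call == "anode" else "cathode" if call == "cathode" else "non_electrode"].add(phage)

    rows = []
    for cat, members in cats.items():
        sums = phage_abundance.loc[sorted(members)].sum(axis=0) if members else (
            phage_abundance.sum(axis=0) * 0.0
        )
        rows.append(
            {
                "category": cat,
                "n_phage_species": len(members),
                "min_percent": float(sums.min()),
                "max_percent": float(sums.max()),
                **{f"sample:{s}": float(v) for s, v in sums.items()},
            }
        )
    return pd.DataFrame(rows)
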