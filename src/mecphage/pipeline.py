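"""End-to-end orchestration: filter -> cluster -> detect -> match ->
abundances -> affiliation -> network -> diversity -> prevalence.

``run_all`` executes every stage in dependency order, writes all tabular
outputs plus a machine-readable summary and a run log, and returns the
in-memory results for further inspection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from mecphage import __version__
from mecphage.abundance import (
    AbundanceTable,
    affiliation_frame,
    classify_affiliation,
    species_abundance,
)
from mecphage.crispr import (
    CrisprParams,
    arrays_to_gff3,
    detect_bin_arrays,
    extract_spacers,
)
from mecphage.derep import (
    GenomeBin,
    PhageContig,
    assign_representatives,
    cluster_species,
    filter_phage_contigs,
    membership_map,
    membership_table,
    retain_prokaryote_species,
)
from mecphage.diversity import (
    dissimilarity_matrix,
    correlate_dissimilarities,
    pcoa,
    prevalence_by_completeness,
)
from mecphage.homology import (
    HomologyParams,
    SpacerQuery,
    ani_table,
    detect_prophage_regions,
    match_induction,
    match_spacers,
)
from mecphage.io import Dataset, read_inputs
from mecphage.network import (
    build_network,
    call_crispr_associations,
    call_prophage_associations,
    edge_table,
    promote_induced,
    summarize_network_abundance,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "results"
    ani_threshold: float = 95.0
    k: int = 17
    sketch_size: int = 1000
    phage_min_length: int = 5000
    min_viral_genes: int = 1
    min_completeness: float = 70.0
    max_contamination: float = 10.0
    affiliation_min_mean: float = 0.1
    group_size: int = 36
    q_list: tuple[float, ...] = (0.0, 1.0, 2.0)
    max_mismatches: int = 1
    crispr_vlp_only: bool = True
    induction_min_ani: float = 95.0
    induction_min_containment: float = 0.8
    n_perm: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        cfg.q_list = tuple(cfg.q_list)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["q_list"] = list(self.q_list)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def prevalence_percent(n_with_feature: int, n_total: int) -> int:
    """Feature prevalence as an integer percentage (nearest percent)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(round(100.0 * n_with_feature / n_total))


@dataclass
class PipelineResult:
    prok_clusters: list
    phage_clusters: list
    arrays: list
    spacers: pd.DataFrame
    regions: list
    induction: dict
    spacer_hits: list
    abundance_prok: AbundanceTable
    abundance_phage: AbundanceTable
    affiliation: list
    associations: list
    summary: dict


def run_all(config: PipelineConfig, dataset: Dataset | None = None) -> PipelineResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read-inputs"
    try:
        ds = dataset if dataset is not None else read_inputs(config.input_dir)
        bins_meta = {b.bin_id: b for b in ds.bins}
        sample_loc = {s.sample_id: s.location for s in ds.samples}
        sample_mec = {s.sample_id: s.mec_id for s in ds.samples}

        stage = "filter-phages"
        retained_phages = filter_phage_contigs(
            ds.phage_contigs, config.phage_min_length, config.min_viral_genes
        )
        phage_meta = {c.contig_id: c for c in retained_phages}

        stage = "cluster-prokaryotes"
        # contigs joined on an N so no chimeric k-mers span the junction
        bin_joined = {b.bin_id: "N".join(b.contigs.values()) for b in ds.bins}
        bin_ani = ani_table(bin_joined, config.k, config.sketch_size)
        prok_clusters = cluster_species(
            list(bin_joined), bin_ani, config.ani_threshold, kind="prokaryote"
        )
        assign_representatives(prok_clusters, bins_meta)
        prok_clusters = retain_prokaryote_species(
            prok_clusters, bins_meta, config.min_completeness, config.max_contamination
        )
        bin_to_species = membership_map(prok_clusters)
        retained_bins = [b for b in ds.bins if b.bin_id in bin_to_species]

        stage = "cluster-phages"
        phage_seqs = {c.contig_id: c.sequence for c in retained_phages}
        phage_ani = ani_table(phage_seqs, config.k, config.sketch_size)
        phage_clusters = cluster_species(
            list(phage_seqs), phage_ani, config.ani_threshold, kind="phage"
        )
        assign_representatives(phage_clusters, phage_meta)
        contig_to_phage_species = membership_map(phage_clusters)

        stage = "crispr-detect"
        crispr_params = CrisprParams()
        arrays = []
        for b in retained_bins:
            arrays.extend(detect_bin_arrays(b.bin_id, b.contigs, crispr_params))
        spacers = extract_spacers(arrays)
        queries = [
            SpacerQuery(r.bin_id, r.array_index, r.spacer_index, r.sequence)
            for r in spacers.itertuples()
        ]

        stage = "prophage-detect"
        hom_params = HomologyParams(
            k=config.k, min_region_length=config.phage_min_length
        )
        rep_seqs = {
            c.representative_id: phage_meta[c.representative_id].sequence
            for c in phage_clusters
        }
        regions = []
        for b in retained_bins:
            for r in detect_prophage_regions(b.bin_id, b.contigs, rep_seqs, hom_params):
                r.phage_species_id = contig_to_phage_species[r.phage_species_id]
                regions.append(r)

        stage = "induction-match"
        vlp_seqs = {
            c.contig_id: c.sequence for c in retained_phages if c.dataset == "VLP"
        }
        induction: dict[str, list[str]] = {}
        for r in regions:
            key = f"{r.bin_id}:{r.contig_id}:{r.start}-{r.end}:{r.phage_species_id}"
            seq = bins_meta[r.bin_id].contigs[r.contig_id][r.start : r.end]
            matches = match_induction(
                seq,
                vlp_seqs,
                config.k,
                config.sketch_size,
                config.induction_min_ani,
                config.induction_min_containment,
            )
            induction[key] = [m.vlp_contig_id for m in matches]

        stage = "spacer-match"
        spacer_hits = match_spacers(queries, phage_seqs, config.max_mismatches)

        stage = "abundance"
        prok_contig_to_species = {
            f"{b.bin_id}|{cid}": bin_to_species[b.bin_id]
            for b in retained_bins
            for cid in b.contigs
        }
        abundance_prok = species_abundance(
            ds.counts_prok, prok_contig_to_species, sample_loc, sample_mec
        )
        if len(ds.counts_vlp.index) == 0:
            abundance_phage = AbundanceTable(
                values=pd.DataFrame(columns=ds.counts_vlp.columns, dtype=float),
                unassigned=pd.Series(100.0, index=ds.counts_vlp.columns),
                sample_locations=dict(sample_loc),
                sample_mecs=dict(sample_mec),
            )
        else:
            abundance_phage = species_abundance(
                ds.counts_vlp, contig_to_phage_species, sample_loc, sample_mec
            )

        stage = "affiliation"
        affiliation = classify_affiliation(abundance_prok, config.affiliation_min_mean)
        affiliation_by_species = {c.species_id: c.call for c in affiliation}

        stage = "associations"
        temperate_by_any = {
            c.species_id: any(
                phage_meta[m].temperate_by_any for m in c.member_ids
            )
            for c in phage_clusters
        }
        associations, skipped = call_prophage_associations(
            regions, temperate_by_any, bin_to_species
        )
        associations, orphans = promote_induced(associations, induction)
        vlp_ids = set(vlp_seqs) if config.crispr_vlp_only else None
        associations += call_crispr_associations(
            spacer_hits, bin_to_species, contig_to_phage_species, vlp_ids
        )
        net_summary = summarize_network_abundance(
            associations, abundance_phage.values, affiliation_by_species
        )

        stage = "diversity"
        diversity_out = _diversity_block(
            config, abundance_prok, abundance_phage, sample_loc, sample_mec, outdir
        )

        stage = "prevalence"
        bins_with_array = {a.bin_id for a in arrays}
        bins_with_region = {r.bin_id for r in regions}
        bin_flags = pd.DataFrame(
            {
                "bin_id": [b.bin_id for b in retained_bins],
                "completeness": [b.completeness for b in retained_bins],
                "prophage": [b.bin_id in bins_with_region for b in retained_bins],
                "crispr": [b.bin_id in bins_with_array for b in retained_bins],
            }
        )
        group_size = min(config.group_size, max(1, len(bin_flags)))
        prev_prophage = prevalence_by_completeness(bin_flags, "prophage", group_size)
        prev_crispr = prevalence_by_completeness(bin_flags, "crispr", group_size)

        stage = "summary"
        summary = _summarize(
            ds,
            retained_phages,
            prok_clusters,
            phage_clusters,
            bin_flags,
            affiliation,
            associations,
            diversity_out["medians"],
            diversity_out["correlations"],
        )

        for name, table in (("ani_prok.tsv", bin_ani), ("ani_phage.tsv", phage_ani)):
            pd.DataFrame(
                [
                    {"id_a": a, "id_b": b, "ani": round(v, 4)}
                    for (a, b), v in sorted(table.items())
                ],
                columns=["id_a", "id_b", "ani"],
            ).to_csv(outdir / name, sep="\t", index=False)

        _write_outputs(
            outdir,
            config,
            prok_clusters,
            phage_clusters,
            arrays,
            spacers,
            regions,
            induction,
            spacer_hits,
            abundance_prok,
            abundance_phage,
            affiliation,
            associations,
            net_summary,
            prev_prophage,
            prev_crispr,
            summary,
            skipped,
            orphans,
        )
    except Exception as exc:  # noqa: BLE001 - annotate failing stage and re-raise
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return PipelineResult(
        prok_clusters=prok_clusters,
        phage_clusters=phage_clusters,
        arrays=arrays,
        spacers=spacers,
        regions=regions,
        induction=induction,
        spacer_hits=spacer_hits,
        abundance_prok=abundance_prok,
        abundance_phage=abundance_phage,
        affiliation=affiliation,
        associations=associations,
        summary=summary,
    )


def _mec_group(table: AbundanceTable, location: str) -> list[str]:
    """One sample per MEC at the given location, ordered by MEC id."""
    cols = [
        s
        for s in table.samples
        if table.sample_locations.get(s) == location
    ]
    return sorted(cols, key=lambda s: table.sample_mecs.get(s, s))


def _diversity_block(config, abundance_prok, abundance_phage, sample_loc, sample_mec, outdir):
    matrices = {}
    for group, table in (
        ("anode", abundance_prok),
        ("cathode", abundance_prok),
        ("phage", abundance_phage),
    ):
        cols = (
            _mec_group(table, group)
            if group in ("anode", "cathode")
            else sorted(table.samples, key=lambda s: sample_mec.get(s, s))
        )
        if len(cols) < 2 or len(table.values.index) == 0:
            continue
        for q in config.q_list:
            m = dissimilarity_matrix(table.values, q, cols)
            matrices[(group, q)] = m
            m.to_frame().to_csv(outdir / f"dissimilarity_{group}_q{q:g}.tsv", sep="\t")
            if len(cols) >= 3:
                res = pcoa(m)
                coords = pd.DataFrame(
                    res.coordinates,
                    index=res.sample_ids,
                    columns=[f"PCo{i + 1}" for i in range(res.coordinates.shape[1])],
                )
                coords.to_csv(outdir / f"pcoa_{group}_q{q:g}.tsv", sep="\t")

    medians = {
        f"{group}_q{q:g}": float(np.median(m.condensed()))
        for (group, q), m in matrices.items()
    }
    correlations = []
    for electrode in ("anode", "cathode"):
        for q in config.q_list:
            me = matrices.get((electrode, q))
            mp = matrices.get(("phage", q))
            if me is None or mp is None:
                continue
            mec_e = [sample_mec.get(s, s) for s in me.sample_ids]
            mec_p = [sample_mec.get(s, s) for s in mp.sample_ids]
            common = [m for m in mec_e if m in set(mec_p)]
            if len(common) < 4:
                continue
            sub_e = _subset_matrix(me, mec_e, common)
            sub_p = _subset_matrix(mp, mec_p, common)
            r, p = correlate_dissimilarities(
                sub_e, sub_p, n_perm=config.n_perm, seed=config.seed
            )
            correlations.append(
                {
                    "comparison": f"{electrode}_vs_phage",
                    "q": q,
                    "r": r,
                    "p": p,
                    "n_mecs": len(common),
                    "n_perm": config.n_perm,
                    "seed": config.seed,
                }
            )
    pd.DataFrame(correlations).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    return {"medians": medians, "correlations": correlations}


def _subset_matrix(m, mec_labels, common):
    from mecphage.diversity import DissimilarityMatrix

    idx = [mec_labels.index(c) for c in common]
    return DissimilarityMatrix(
        sample_ids=list(common), q=m.q, values=m.values[np.ix_(idx, idx)]
    )


def _summarize(
    ds,
    retained_phages,
    prok_clusters,
    phage_clusters,
    bin_flags,
    affiliation,
    associations,
    medians,
    correlations,
):
    species_flag = {}
    bin_species = membership_map(prok_clusters)
    for r in bin_flags.itertuples():
        sp = bin_species.get(r.bin_id)
        if sp is None:
            continue
        flags = species_flag.setdefault(sp, {"prophage": False, "crispr": False})
        flags["prophage"] |= bool(r.prophage)
        flags["crispr"] |= bool(r.crispr)

    pairs_by_evidence: dict[str, set] = {}
    for a in associations:
        pairs_by_evidence.setdefault(a.evidence, set()).add(a.pair)
    all_pairs = {a.pair for a in associations}

    n_bins = len(bin_flags)
    n_species = len(prok_clusters)
    n_bins_prophage = int(bin_flags["prophage"].sum())
    n_bins_crispr = int(bin_flags["crispr"].sum())
    n_species_prophage = sum(f["prophage"] for f in species_flag.values())
    n_species_crispr = sum(f["crispr"] for f in species_flag.values())
    calls = pd.Series([c.call for c in affiliation])
    return {
        "version": __version__,
        "n_bins": n_bins,
        "n_prokaryote_species": n_species,
        "n_phage_contigs_retained": len(retained_phages),
        "n_phage_species": len(phage_clusters),
        "n_bins_with_prophage": n_bins_prophage,
        "n_bins_with_crispr": n_bins_crispr,
        "n_species_with_prophage": n_species_prophage,
        "n_species_with_crispr": n_species_crispr,
        "percent_bins_with_prophage": prevalence_percent(n_bins_prophage, n_bins) if n_bins else None,
        "percent_bins_with_crispr": prevalence_percent(n_bins_crispr, n_bins) if n_bins else None,
        "percent_species_with_prophage": prevalence_percent(n_species_prophage, n_species) if n_species else None,
        "percent_species_with_crispr": prevalence_percent(n_species_crispr, n_species) if n_species else None,
        "n_anode_affiliated": int((calls == "anode").sum()),
        "n_cathode_affiliated": int((calls == "cathode").sum()),
        "n_associated_hosts": len({p[0] for p in all_pairs}),
        "n_associated_phages": len({p[1] for p in all_pairs}),
        "n_association_pairs": len(all_pairs),
        "associations_by_evidence": {
            ev: len(pairs) for ev, pairs in sorted(pairs_by_evidence.items())
        },
        "dissimilarity_medians": medians,
        "correlations": correlations,
    }


def _write_outputs(
    outdir,
    config,
    prok_clusters,
    phage_clusters,
    arrays,
    spacers,
    regions,
    induction,
    spacer_hits,
    abundance_prok,
    abundance_phage,
    affiliation,
    associations,
    net_summary,
    prev_prophage,
    prev_crispr,
    summary,
    skipped,
    orphans,
):
    import networkx as nx

    membership_table(prok_clusters).to_csv(outdir / "clusters_prok.tsv", sep="\t", index=False)
    membership_table(phage_clusters).to_csv(outdir / "clusters_phage.tsv", sep="\t", index=False)
    (outdir / "crispr_arrays.gff3").write_text(arrays_to_gff3(arrays))
    spacers.to_csv(outdir / "spacers.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "contig": f"{r.bin_id}|{r.contig_id}",
                "start": r.start,
                "end": r.end,
                "name": r.phage_species_id,
                "score": round(r.containment, 4),
                "strand": ".",
            }
            for r in regions
        ],
        columns=["contig", "start", "end", "name", "score", "strand"],
    ).to_csv(outdir / "prophage_regions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"region": k, "vlp_contigs": ";".join(v)} for k, v in induction.items()],
        columns=["region", "vlp_contigs"],
    ).to_csv(outdir / "induction_matches.tsv", sep="\t", index=False)
    pd.DataFrame([vars(h) for h in spacer_hits]).to_csv(
        outdir / "spacer_hits.tsv", sep="\t", index=False
    )
    abundance_prok.values.to_csv(outdir / "abundance_prok.tsv", sep="\t")
    abundance_phage.values.to_csv(outdir / "abundance_phage.tsv", sep="\t")
    affiliation_frame(affiliation).to_csv(outdir / "affiliation.tsv", sep="\t", index=False)
    edge_table(associations).to_csv(outdir / "associations.tsv", sep="\t", index=False)
    g = build_network(associations)
    nx.write_graphml(g, outdir / "network.graphml")
    net_summary.to_csv(outdir / "network_abundance_summary.tsv", sep="\t", index=False)
    prev_prophage.groups.to_csv(outdir / "prevalence_prophage.tsv", sep="\t", index=False)
    prev_crispr.groups.to_csv(outdir / "prevalence_crispr.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {**asdict(config), "q_list": list(config.q_list)},
        "skipped_virulent_regions": skipped,
        "orphan_induction_matches": orphans,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
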