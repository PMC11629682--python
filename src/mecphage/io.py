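"""Dataset I/O: FASTA/TSV readers and writers, schema validation, manifest.

File layout of a dataset directory::

    bins.fasta        headers "binID|contigID"
    phages.fasta      headers "phageContigID"
    bins.tsv          bin_id, sample_id, completeness, contamination, taxonomy
    phages.tsv        contig_id, dataset, viral_gene_count,
                      lifestyle_phatyp, lifestyle_vibrant, lifestyle_phageboost,
                      completeness
    counts_prok.tsv   contig ("binID|contigID") x prokaryotic samples
    counts_vlp.tsv    contig x VLP samples
    samples.tsv       sample_id, mec_id, location, dataset
    config.yaml       generator config (synthetic datasets only)
    truth/*.tsv       ground truth (synthetic datasets only)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mecphage.derep import GenomeBin, PhageContig
from mecphage.errors import DanglingReferenceError, DuplicateIdError, ValidationError

LOCATIONS = ("anode", "cathode", "tubing", "suspension", "inoculum", "foam")
LIFESTYLE_COLUMNS = ("lifestyle_phatyp", "lifestyle_vibrant", "lifestyle_phageboost")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    mec_id: str
    location: str
    dataset: str  # "prokaryotic" or "VLP"


@dataclass
class Dataset:
    samples: list[SampleRecord]
    bins: list[GenomeBin]
    phage_contigs: list[PhageContig]
    counts_prok: pd.DataFrame
    counts_vlp: pd.DataFrame


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: Path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DuplicateIdError(f"duplicate FASTA header {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: Path, sequences: dict[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV helpers


def _read_tsv(path: Path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return df


def read_counts(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "contig"
    return df


# ---------------------------------------------------------------------------
# dataset reading with cross-validation


def read_inputs(directory: str | Path) -> Dataset:
    """Load and cross-validate a dataset directory.

    Raises named errors: ``duplicate-id`` for repeated ids,
    ``dangling-reference`` for records pointing at absent ids, and a
    validation error for missing columns, listing the offenders.
    """
    d = Path(directory)
    bin_seqs = read_fasta(d / "bins.fasta")
    phage_seqs = read_fasta(d / "phages.fasta")

    samples_df = _read_tsv(d / "samples.tsv", ["sample_id", "mec_id", "location", "dataset"])
    if samples_df["sample_id"].duplicated().any():
        dups = samples_df.loc[samples_df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateIdError(f"duplicate sample ids: {dups}")
    key = samples_df[["mec_id", "location", "dataset"]]
    if key.duplicated().any():
        raise DuplicateIdError("duplicate (mec, location, dataset) sample keys")
    bad_loc = samples_df.loc[~samples_df["location"].isin(LOCATIONS), "location"]
    if len(bad_loc):
        raise ValidationError(f"unknown sample locations: {sorted(set(bad_loc))}")
    samples = [
        SampleRecord(r.sample_id, r.mec_id, r.location, r.dataset)
        for r in samples_df.itertuples()
    ]

    bins_df = _read_tsv(
        d / "bins.tsv", ["bin_id", "sample_id", "completeness", "contamination"]
    )
    if bins_df["bin_id"].duplicated().any():
        raise DuplicateIdError("duplicate bin ids in bins.tsv")

    # group bin contigs
    contigs_by_bin: dict[str, dict[str, str]] = {}
    for header, seq in bin_seqs.items():
        if "|" not in header:
            raise ValidationError(f"bin FASTA header {header!r} lacks 'binID|contigID'")
        bin_id, contig_id = header.split("|", 1)
        contigs_by_bin.setdefault(bin_id, {})[contig_id] = seq

    meta_bins = set(bins_df["bin_id"])
    fasta_bins = set(contigs_by_bin)
    if meta_bins - fasta_bins:
        raise DanglingReferenceError(
            f"bins.tsv references bins absent from bins.fasta: {sorted(meta_bins - fasta_bins)}"
        )
    if fasta_bins - meta_bins:
        raise DanglingReferenceError(
            f"bins.fasta contains bins absent from bins.tsv: {sorted(fasta_bins - meta_bins)}"
        )
    sample_ids = {s.sample_id for s in samples}
    bad = sorted(set(bins_df["sample_id"]) - sample_ids)
    if bad:
        raise DanglingReferenceError(f"bins.tsv references unknown samples: {bad}")

    bins = [
        GenomeBin(
            bin_id=r.bin_id,
            sample_id=r.sample_id,
            contigs=contigs_by_bin[r.bin_id],
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            taxonomy=getattr(r, "taxonomy", None),
        )
        for r in bins_df.itertuples()
    ]

    phages_df = _read_tsv(
        d / "phages.tsv", ["contig_id", "dataset", "viral_gene_count", "completeness"]
    )
    if phages_df["contig_id"].duplicated().any():
        raise DuplicateIdError("duplicate phage contig ids in phages.tsv")
    meta_p, fasta_p = set(phages_df["contig_id"]), set(phage_seqs)
    if meta_p ^ fasta_p:
        raise DanglingReferenceError(
            f"phages.tsv / phages.fasta id mismatch: {sorted(meta_p ^ fasta_p)}"
        )
    lifestyle_cols = [c for c in LIFESTYLE_COLUMNS if c in phages_df.columns]
    phage_contigs = []
    for r in phages_df.itertuples():
        lifestyles = {
            c.removeprefix("lifestyle_"): getattr(r, c)
            for c in lifestyle_cols
            if isinstance(getattr(r, c), str)
        }
        phage_contigs.append(
            PhageContig(
                contig_id=r.contig_id,
                dataset=r.dataset,
                sequence=phage_seqs[r.contig_id],
                viral_gene_count=int(r.viral_gene_count),
                lifestyles=lifestyles,
                completeness=float(r.completeness),
            )
        )

    counts_prok = read_counts(d / "counts_prok.tsv")
    counts_vlp = read_counts(d / "counts_vlp.tsv")
    bin_contig_ids = set(bin_seqs)
    bad = sorted(set(counts_prok.index) - bin_contig_ids)
    if bad:
        raise DanglingReferenceError(f"counts_prok.tsv references unknown contigs: {bad[:5]}")
    bad = sorted(set(counts_vlp.index) - set(phage_seqs))
    if bad:
        raise DanglingReferenceError(f"counts_vlp.tsv references unknown contigs: {bad[:5]}")
    prok_sample_ids = {s.sample_id for s in samples if s.dataset == "prokaryotic"}
    vlp_sample_ids = {s.sample_id for s in samples if s.dataset == "VLP"}
    bad = sorted(set(counts_prok.columns) - prok_sample_ids)
    if bad:
        raise DanglingReferenceError(f"counts_prok.tsv references unknown samples: {bad}")
    bad = sorted(set(counts_vlp.columns) - vlp_sample_ids)
    if bad:
        raise DanglingReferenceError(f"counts_vlp.tsv references unknown samples: {bad}")

    return Dataset(
        samples=samples,
        bins=bins,
        phage_contigs=phage_contigs,
        counts_prok=counts_prok,
        counts_vlp=counts_vlp,
    )


# ---------------------------------------------------------------------------
# dataset writing


def write_dataset(ds, outdir: Path) -> None:
    """Write a (synthetic or loaded) dataset to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bin_fasta = {}
    bin_rows = []
    for b in ds.bins:
        for cid, seq in b.contigs.items():
            bin_fasta[f"{b.bin_id}|{cid}"] = seq
        bin_rows.append(
            {
                "bin_id": b.bin_id,
                "sample_id": b.sample_id,
                "completeness": round(b.completeness, 4),
                "contamination": round(b.contamination, 4),
                "taxonomy": b.taxonomy or "",
            }
        )
    write_fasta(outdir / "bins.fasta", bin_fasta)
    pd.DataFrame(bin_rows).to_csv(outdir / "bins.tsv", sep="\t", index=False)

    phage_fasta = {c.contig_id: c.sequence for c in ds.phage_contigs}
    write_fasta(outdir / "phages.fasta", phage_fasta)
    phage_rows = []
    for c in ds.phage_contigs:
        row = {
            "contig_id": c.contig_id,
            "dataset": c.dataset,
            "viral_gene_count": c.viral_gene_count,
            "completeness": round(c.completeness, 4),
        }
        for pred in ("phatyp", "vibrant", "phageboost"):
            row[f"lifestyle_{pred}"] = c.lifestyles.get(pred, "")
        phage_rows.append(row)
    pd.DataFrame(phage_rows).to_csv(outdir / "phages.tsv", sep="\t", index=False)

    pd.DataFrame([vars(s) for s in ds.samples]).to_csv(
        outdir / "samples.tsv", sep="\t", index=False
    )
    ds.counts_prok.to_csv(outdir / "counts_prok.tsv", sep="\t")
    ds.counts_vlp.to_csv(outdir / "counts_vlp.tsv", sep="\t")

    truth = getattr(ds, "truth", None)
    if truth is not None:
        truth.write_tsv(outdir / "truth")
    config = getattr(ds, "config", None)
    if config is not None:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(_plain(config.to_dict()), fh, sort_keys=True)


def _plain(obj):
    """Recursively convert tuples to lists for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
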