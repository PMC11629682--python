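"""Synthetic community generator: contracts, determinism, truncation model."""

import filecmp
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from mecphage.errors import InfeasibleConfigError
from mecphage.seqs import random_seq
from mecphage.synth import SynthConfig, generate_dataset, truncate_bin
from tests.conftest import SMALL_KWARGS


def _cfg(**over):
    return SynthConfig(**{**SMALL_KWARGS, **over})


class TestGenerateDataset:
    def test_probability_zero_case(self):
        ds = generate_dataset(_cfg(prophage_prob=0.0, crispr_prob=0.0))
        assert len(ds.truth.prophages) == 0
        assert len(ds.truth.crispr_links) == 0
        assert len(ds.truth.planted_arrays) == 0

    def test_probability_one_induction(self):
        ds = generate_dataset(_cfg(induction_prob=1.0, prophage_prob=1.0))
        vlp_species = {
            c.contig_id.rsplit("_", 1)[0]
            for c in ds.phage_contigs
            if c.dataset == "VLP" and not c.contig_id.startswith("junk")
        }
        planted = set(ds.truth.prophages["phage_species"])
        assert planted and planted <= vlp_species

    def test_determinism_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_dataset(_cfg(seed=11), a)
        generate_dataset(_cfg(seed=11), b)
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel

    def test_sample_totals_positive(self, small_dataset):
        totals = small_dataset.counts_prok.sum(axis=0)
        prok_samples = [s for s in small_dataset.samples if s.dataset == "prokaryotic"]
        assert set(totals.index) == {s.sample_id for s in prok_samples}
        assert (totals > 0).all()
        assert (small_dataset.counts_vlp.sum(axis=0) > 0).all()

    def test_completeness_matches_retained_fraction(self, small_dataset):
        # per-bin completeness metadata equals the retained fraction of the
        # species' full genome; with targets in [85,100] and +-1pt tolerance
        lo = SMALL_KWARGS["completeness_range"][0]
        for b in small_dataset.bins:
            assert lo - 1.5 <= b.completeness <= 100.0

    def test_host_genomes_multi_contig(self, small_dataset):
        seen_species = set()
        for b in small_dataset.bins:
            sp = b.bin_id.rsplit("_b", 1)[0]
            seen_species.add(sp)
            assert 1 <= len(b.contigs) <= 20
        assert len(seen_species) == SMALL_KWARGS["n_host_species"]

    def test_phage_lengths_in_range(self, small_dataset):
        for c in small_dataset.phage_contigs:
            if c.contig_id.startswith("junk"):
                continue
            # mutated copies keep the canonical length
            assert 5_000 <= len(c) <= 161_000

    @pytest.mark.parametrize(
        "over",
        [
            dict(prophage_prob=1.5),
            dict(n_mecs=1),
            dict(completeness_range=(0.0, 100.0)),
            dict(phage_size_range=(20_000, 30_000)),  # larger than min genome
            dict(bins_per_species=(4, 5)),  # more bins than MECs
            dict(spacer_length_range=(20, 48)),
        ],
    )
    def test_infeasible_configs_rejected(self, over):
        with pytest.raises(InfeasibleConfigError):
            generate_dataset(_cfg(**over))


class TestTruncateBin:
    def test_identity_at_full_completeness(self):
        rng = np.random.default_rng(0)
        contigs = {"c1": random_seq(rng, 20_000), "c2": random_seq(rng, 10_000)}
        t = truncate_bin(contigs, 100.0, 1)
        assert t.contigs == contigs
        assert t.retained_fraction == 1.0

    def test_half_completeness_length(self):
        rng = np.random.default_rng(1)
        contigs = {"c1": random_seq(rng, 100_000)}
        t = truncate_bin(contigs, 50.0, 2)
        assert 49_000 <= t.retained_length <= 51_000

    def test_retention_monotone_in_completeness(self):
        # mean planted-interval retention is non-decreasing in the target
        rng = np.random.default_rng(3)
        contigs = {"c1": random_seq(rng, 30_000)}
        interval = (12_000, 15_000)
        means = []
        for target in (50.0, 70.0, 90.0, 100.0):
            vals = []
            for rep in range(100):
                t = truncate_bin(contigs, target, 1000 + rep)
                ret, *_ = t.project("c1", *interval)
                vals.append(ret / (interval[1] - interval[0]))
            means.append(np.mean(vals))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))

    def test_monte_carlo_oracle_full_retention(self):
        """Fraction of truncations fully retaining a planted interval matches
        an independent interval-only simulation of the same block model."""
        genome_len, block = 100_000, (200, 2000)
        a, b = 45_000, 55_000  # 10% prophage
        target = 50.0

        def oracle(seed):
            # pure-interval re-implementation: no sequences involved
            rng = np.random.default_rng(seed)
            segs = [(0, genome_len)]
            retained = genome_len
            goal = genome_len * target / 100.0
            while retained > goal + 0.5:
                deficit = int(np.ceil(retained - goal))
                size = min(deficit, int(rng.integers(block[0], block[1] + 1)))
                rng.choice(1, p=[1.0])  # mirror the contig-choice draw
                off = int(rng.integers(0, max(1, retained)))
                new, removed, pos = [], 0, 0
                for s, e in segs:
                    L = e - s
                    lo, hi = max(0, off - pos), min(L, off + size - pos)
                    if lo < hi:
                        if lo > 0:
                            new.append((s, s + lo))
                        if hi < L:
                            new.append((s + hi, e))
                        removed += hi - lo
                    else:
                        new.append((s, e))
                    pos += L
                segs = new
                retained -= removed
                if removed == 0:
                    break
            return any(s <= a and b <= e for s, e in segs)

        rng = np.random.default_rng(9)
        contigs = {"c1": random_seq(rng, genome_len)}
        n = 200
        actual = np.mean(
            [
                truncate_bin(contigs, target, 5000 + i).project("c1", a, b)[4]
                for i in range(n)
            ]
        )
        expected = np.mean([oracle(5000 + i) for i in range(n)])
        assert abs(actual - expected) < 0.1

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            truncate_bin({"c1": "ACGT" * 1000}, 0.0, 1)
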