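"""Sketch ANI, prophage calling, induction and spacer matching oracles."""

import numpy as np
import pytest

from mecphage.errors import IncompatibleSketchesError, TooShortError
from mecphage.homology import (
    HomologyParams,
    SpacerQuery,
    ani_table,
    detect_prophage_regions,
    estimate_ani,
    match_induction,
    match_spacers,
    sketch,
)
from mecphage.seqs import mutate, random_seq, revcomp


def naive_spacer_scan(spacer, contig, max_mm):
    """Independent O(n*m) sliding-window oracle (pure python)."""
    hits = []
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        for i in range(len(contig) - len(query) + 1):
            mm = sum(
                1
                for a, b in zip(query, contig[i : i + len(query)])
                if a != b or a == "N" or b == "N"
            )
            if mm <= max_mm:
                hits.append((i, strand, mm))
    return sorted(hits)


class TestSketch:
    def test_revcomp_equality(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 5000)
        a, b = sketch(s), sketch(revcomp(s))
        assert np.array_equal(a.hashes, b.hashes)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 5000)
        assert np.array_equal(sketch(s).hashes, sketch(s).hashes)

    def test_full_sketch_size(self):
        rng = np.random.default_rng(2)
        s = random_seq(rng, 20_000)
        sk = sketch(s, k=17, sketch_size=1000)
        assert len(sk.hashes) == 1000

    def test_too_short(self):
        with pytest.raises(TooShortError):
            sketch("ACGT", k=17)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            sketch("ACGT" * 100, k=7)


class TestEstimateAni:
    def test_identical_sequences(self):
        rng = np.random.default_rng(3)
        s = random_seq(rng, 20_000)
        assert estimate_ani(sketch(s), sketch(s)).ani == 100.0

    def test_mutation_mask_oracle_3_percent(self):
        rng = np.random.default_rng(4)
        s = random_seq(rng, 20_000)
        m, hits = mutate(s, 0.03, rng)
        true_identity = 100.0 * (1 - len(hits) / len(s))  # exact mask oracle
        est = estimate_ani(sketch(s), sketch(m)).ani
        assert 95.5 <= est <= 98.5
        assert abs(est - true_identity) <= 2.0

    def test_unrelated_sequences(self):
        rng = np.random.default_rng(5)
        a, b = random_seq(rng, 20_000), random_seq(rng, 20_000)
        assert estimate_ani(sketch(a), sketch(b)).ani < 75.0

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            s = random_seq(rng, 8000)
            m, _ = mutate(s, 0.02, rng)
            assert (
                estimate_ani(sketch(s), sketch(m)).ani
                == estimate_ani(sketch(m), sketch(s)).ani
            )

    def test_monotone_in_substitution_rate(self):
        rng = np.random.default_rng(7)
        s = random_seq(rng, 20_000)
        anis = []
        for i, rate in enumerate(np.arange(0.0, 0.101, 0.01)):
            m, _ = mutate(s, rate, np.random.default_rng(100 + i))
            anis.append(estimate_ani(sketch(s), sketch(m)).ani)
        assert all(b <= a + 0.1 for a, b in zip(anis, anis[1:]))

    def test_incompatible_sketches(self):
        rng = np.random.default_rng(8)
        s = random_seq(rng, 5000)
        with pytest.raises(IncompatibleSketchesError):
            estimate_ani(sketch(s, k=17), sketch(s, k=21))


class TestDetectProphageRegions:
    def test_planted_verbatim_prophage(self):
        rng = np.random.default_rng(9)
        phage = random_seq(rng, 12_000)
        host = random_seq(rng, 30_000)
        pos = 10_000
        contig = host[:pos] + phage + host[pos:]
        regions = detect_prophage_regions("b1", {"c1": contig}, {"P1": phage})
        assert len(regions) == 1
        r = regions[0]
        assert abs(r.start - pos) <= 200
        assert abs(r.end - (pos + len(phage))) <= 200
        assert r.containment >= 0.99
        assert r.phage_species_id == "P1"

    def test_no_planted_phage(self):
        rng = np.random.default_rng(10)
        contig = random_seq(rng, 30_000)
        phage = random_seq(rng, 12_000)
        assert detect_prophage_regions("b1", {"c1": contig}, {"P1": phage}) == []

    def test_short_fragment_rejected(self):
        rng = np.random.default_rng(11)
        phage = random_seq(rng, 12_000)
        host = random_seq(rng, 30_000)
        contig = host[:5000] + phage[:4000] + host[5000:]
        assert detect_prophage_regions("b1", {"c1": contig}, {"P1": phage}) == []

    def test_empty_phage_set_rejected(self):
        with pytest.raises(ValueError):
            detect_prophage_regions("b1", {"c1": "ACGT" * 100}, {})

    def test_recall_precision_planted(self):
        """Planted prophages at 1% substitutions: recall and precision >= 0.95."""
        rng = np.random.default_rng(12)
        phages = {f"P{i}": random_seq(rng, 10_000) for i in range(8)}
        truth, n_bins = [], 12
        contig_sets = []
        for b in range(n_bins):
            host = random_seq(rng, 25_000)
            pid = f"P{b % 8}"
            ins, _ = mutate(phages[pid], 0.01, rng)
            pos = int(rng.integers(0, len(host)))
            contig_sets.append({"c1": host[:pos] + ins + host[pos:]})
            truth.append((f"b{b}", pid))
        detected = set()
        for b, contigs in enumerate(contig_sets):
            for r in detect_prophage_regions(f"b{b}", contigs, phages):
                detected.add((r.bin_id, r.phage_species_id))
        tp = detected & set(truth)
        assert len(tp) / len(truth) >= 0.95
        assert len(tp) / max(1, len(detected)) >= 0.95


class TestMatchInduction:
    def test_identical(self):
        rng = np.random.default_rng(13)
        p = random_seq(rng, 10_000)
        (m,) = match_induction(p, {"v1": p})
        assert m.ani == 100.0 and m.containment == 1.0

    def test_unrelated(self):
        rng = np.random.default_rng(14)
        assert match_induction(random_seq(rng, 10_000), {"v1": random_seq(rng, 10_000)}) == []

    def test_two_percent_substitutions(self):
        rng = np.random.default_rng(15)
        p = random_seq(rng, 10_000)
        v, hits = mutate(p, 0.02, rng)
        assert 100.0 * (1 - len(hits) / len(p)) >= 95.0  # mask oracle premise
        matches = match_induction(p, {"v1": v})
        assert [m.vlp_contig_id for m in matches] == ["v1"]


class TestMatchSpacers:
    def test_exact_forward_hit(self):
        rng = np.random.default_rng(16)
        phage = random_seq(rng, 5000)
        spacer = phage[1000:1032]
        hits = match_spacers([SpacerQuery("b1", 0, 0, spacer)], {"P1": phage})
        assert [(h.position, h.strand, h.mismatches) for h in hits] == [(1000, "+", 0)]

    def test_revcomp_hit(self):
        rng = np.random.default_rng(17)
        phage = random_seq(rng, 5000)
        spacer = revcomp(phage[2000:2032])
        hits = match_spacers([SpacerQuery("b1", 0, 0, spacer)], {"P1": phage})
        assert [(h.position, h.strand, h.mismatches) for h in hits] == [(2000, "-", 0)]

    def test_random_spacer_no_hits(self):
        rng = np.random.default_rng(18)
        phage = random_seq(rng, 50_000)
        spacer = random_seq(rng, 32)
        hits = match_spacers([SpacerQuery("b1", 0, 0, spacer)], {"P1": phage})
        assert hits == []
        assert naive_spacer_scan(spacer, phage, 1) == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_agrees_with_naive_oracle(self, max_mm):
        rng = np.random.default_rng(19)
        phage = random_seq(rng, 20_000)
        spacers = []
        # planted exact, 1-mismatch, revcomp, and random spacers
        s0 = phage[500:532]
        s1 = list(phage[4000:4032])
        s1[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s1[10]]
        spacers = [s0, "".join(s1), revcomp(phage[9000:9040]), random_seq(rng, 30)]
        for si, sp in enumerate(spacers):
            got = match_spacers([SpacerQuery("b1", 0, si, sp)], {"P1": phage}, max_mm)
            expected = naive_spacer_scan(sp, phage, max_mm)
            assert [(h.position, h.strand, h.mismatches) for h in got] == expected

    def test_ambiguous_bases_never_match(self):
        phage = "ACGT" * 20
        spacer = "N" * 28
        assert match_spacers([SpacerQuery("b1", 0, 0, spacer)], {"P1": phage}) == []


def test_ani_table_keys_sorted_pairs():
    rng = np.random.default_rng(20)
    seqs = {"b": random_seq(rng, 3000), "a": random_seq(rng, 3000)}
    table = ani_table(seqs)
    assert set(table) == {("a", "b")}
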