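import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from patrrkit.enrichment import (MOTIF, NullModelConfig, copy_number_ratio,
                                 count_motif, enrichment_test,
                                 expected_motif_count,
                                 generate_random_sequence, sample_null_counts,
                                 wilcoxon_signed_rank)
from patrrkit.seq import NucleotideSequence, composition


def brute_force_count(s: str, motif: str) -> int:
    """Position-by-position scan; the independent counting oracle."""
    k = len(motif)
    return sum(1 for i in range(len(s) - k + 1) if s[i:i + k] == motif)


def enumerate_signed_rank_p(observed, nulls, alternative="two-sided"):
    """Exact signed-rank p by explicit enumeration of all sign vectors."""
    diffs = [observed - x for x in nulls]
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    absd = sorted(range(n), key=lambda i: abs(diffs[i]))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs(diffs[absd[j + 1]]) == abs(diffs[absd[i]]):
            j += 1
        for t in range(i, j + 1):
            ranks[absd[t]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    ge = sum(1 for w in ws if w >= w_obs - 1e-9) / len(ws)
    le = sum(1 for w in ws if w <= w_obs + 1e-9) / len(ws)
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(ge, le))


class TestCountMotif:
    @pytest.mark.parametrize("s,motif,expected", [
        ("TATAATATA", MOTIF, 1),
        ("TATAATATATAATATA", MOTIF, 2),  # overlapping starts 1 and 8
        ("GGGGGGGGG", MOTIF, 0),
        ("TATA", MOTIF, 0),  # motif longer than sequence
    ])
    def test_examples(self, s, motif, expected):
        n, hits = count_motif(s, motif)
        assert n == expected == len(hits)
        for h in hits:
            assert s[h.position - 1:h.position - 1 + len(motif)] == motif

    def test_overlapping_positions(self):
        _, hits = count_motif("TATAATATATAATATA", MOTIF)
        assert [h.position for h in hits] == [1, 8]

    def test_both_strands_deduplicates(self):
        # TATATTATA is revcomp(MOTIF); occurs once forward in this string
        s = "GGTATATTATAGG"
        n_fwd, _ = count_motif(s, MOTIF, "forward")
        n_both, hits = count_motif(s, MOTIF, "both")
        assert n_fwd == 0 and n_both == 1
        assert hits[0].strand == "-"

    def test_n_never_matches(self):
        assert count_motif("TATANTATA", "TATANTATA" .replace("N", "A"))[0] == 0

    @given(st.text(alphabet="AT", min_size=9, max_size=120),
           st.sampled_from([MOTIF, "TATTATATA", "ATA", "TTT"]))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force(self, s, motif):
        assert count_motif(s, motif)[0] == brute_force_count(s, motif)

    def test_brute_force_on_long_sequence(self):
        s = generate_random_sequence(10_000, 0.07, seed=2).residues
        assert count_motif(s, MOTIF)[0] == brute_force_count(s, MOTIF)


class TestRandomSequences:
    def test_at_only_when_gc_zero(self):
        s = generate_random_sequence(10, 0.0, 1)
        assert set(s.residues) <= set("AT")

    def test_sample_fold_composition(self):
        # 1393 nt at 8.3% G+C, the scale of a typical random-fold control
        s = generate_random_sequence(1393, 0.083, 7)
        assert composition(s).gc_fraction == pytest.approx(0.083, abs=0.02)

    def test_deterministic(self):
        a = generate_random_sequence(500, 0.3, 9)
        b = generate_random_sequence(500, 0.3, 9)
        assert a.residues == b.residues

    def test_gc_out_of_range(self):
        with pytest.raises(ValueError):
            generate_random_sequence(10, 1.5, 0)


class TestExpectedCount:
    def test_closed_form_single_window(self):
        assert expected_motif_count(9, 0.0, MOTIF) == pytest.approx(
            0.5 ** 9)

    def test_second_locus_scale(self):
        # 1684 windows x 0.465^9, computed independently
        assert expected_motif_count(1692, 0.07, MOTIF) == pytest.approx(
            1684 * ((1 - 0.07) / 2) ** 9, rel=1e-12)
        assert expected_motif_count(1692, 0.07, MOTIF) == pytest.approx(
            1.71, abs=0.01)

    def test_gc_motif_impossible_without_gc(self):
        assert expected_motif_count(100, 0.0, "TAG") == 0.0

    def test_shorter_than_motif(self):
        assert expected_motif_count(5, 0.5, MOTIF) == 0.0


class TestNullSampling:
    def test_mean_matches_analytic_oracle(self):
        cfg = NullModelConfig(length=1692, gc_fraction=0.07, n_samples=400,
                              seed=123)
        counts = sample_null_counts(cfg)
        mu = expected_motif_count(1692, 0.07)
        se = math.sqrt(mu / 400)  # counts are near-Poisson
        assert abs(np.mean(counts) - mu) <= 3 * se

    def test_degenerate_window(self):
        cfg = NullModelConfig(length=9, gc_fraction=0.0, n_samples=50, seed=1)
        assert set(sample_null_counts(cfg)) <= {0, 1}

    def test_reproducible(self):
        cfg = NullModelConfig(length=300, gc_fraction=0.1, n_samples=10,
                              seed=77)
        assert sample_null_counts(cfg) == sample_null_counts(cfg)


class TestWilcoxon:
    def test_three_positive_differences(self):
        # enumeration of 8 sign vectors: max statistic, two-sided 2/8
        assert wilcoxon_signed_rank(10, [1, 2, 3]) == pytest.approx(0.25)

    def test_twenty_five_positive_differences(self):
        p = wilcoxon_signed_rank(38, [1, 0, 2, 3, 1] * 5)
        assert p == pytest.approx(2 / 2 ** 25)
        assert p < 1e-4

    def test_all_ties_undefined(self):
        assert wilcoxon_signed_rank(5, [5, 5, 5]) is None

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        nulls = rng.integers(0, 4, size=n).tolist()  # heavy tie patterns
        obs = int(rng.integers(0, 5))
        got = wilcoxon_signed_rank(obs, nulls)
        want = enumerate_signed_rank_p(obs, nulls)
        if want is None or all(obs == x for x in nulls):
            assert got is None
        else:
            assert got == pytest.approx(want)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        obs = 20.0
        nulls = np.round(rng.uniform(0, 15, size=12), 3).tolist()
        got = wilcoxon_signed_rank(obs, nulls)
        want = stats.wilcoxon([obs - x for x in nulls],
                              mode="exact").pvalue
        assert got == pytest.approx(want)

    def test_one_sided_options(self):
        assert wilcoxon_signed_rank(10, [1, 2, 3], "greater") == \
            pytest.approx(0.125)


class TestEnrichment:
    def test_planted_region_strongly_enriched(self):
        from patrrkit.simulate import make_variable_region
        seq, truth = make_variable_region(1692, 0.07, MOTIF, 58, seed=4)
        res = enrichment_test(seq, MOTIF, n_samples=25, seed=9)
        assert res.observed_count >= 58
        assert res.fold_enrichment > 20
        assert res.p_value < 1e-6

    def test_no_motif_not_significant(self):
        s = NucleotideSequence("g", "G" * 400 + "A" * 400)
        res = enrichment_test(s, MOTIF, n_samples=25, seed=1)
        assert res.observed_count == 0
        assert res.fold_enrichment == 0 or res.p_value is None or \
            res.p_value > 0.05

    def test_fold_of_printed_counts(self):
        assert 38 / 0.8 == pytest.approx(47.5)  # "almost 50-fold" bookkeeping
        assert copy_number_ratio(38, 20) == 1.9
        assert copy_number_ratio(20, 8) == 2.5
        assert copy_number_ratio(26, 23) == 1.1
        assert copy_number_ratio(5, 0) is None

    def test_invariant_to_id_and_context(self):
        from patrrkit.simulate import make_variable_region
        seq, _ = make_variable_region(600, 0.06, MOTIF, 10, seed=8)
        renamed = NucleotideSequence("other_name", seq.residues)
        r1 = enrichment_test(seq, MOTIF, 25, seed=3)
        r2 = enrichment_test(renamed, MOTIF, 25, seed=3)
        assert r1.observed_count == r2.observed_count
        assert r1.null_counts == r2.null_counts
        assert r1.p_value == r2.p_value
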