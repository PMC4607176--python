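import numpy as np
import pytest

from patrrkit.enrichment import MOTIF, count_motif
from patrrkit.homology import (Alignment, classify_motif_fate, global_align,
                               local_map, percent_identity)
from patrrkit.seq import NucleotideSequence, reverse_complement
from tests.conftest import random_dna

MATCH, MISMATCH, OPEN, EXT = 5.0, -4.0, 10.0, 0.5


def oracle_best_score(a: str, b: str) -> float:
    """Exhaustive enumeration of every alignment path (affine gaps, free end
    gaps), scored independently of the implementation. Exponential; only for
    tiny strings."""
    best = [-1e18]

    def score_alignment(cols):
        # EMBOSS rules: gap of length L costs OPEN + EXT*L; gap runs at the
        # ends of either aligned string are free
        sa = "".join(x for x, _ in cols)
        sb = "".join(y for _, y in cols)
        s = 0.0
        for x, y in cols:
            if x != "-" and y != "-":
                s += MATCH if x == y else MISMATCH
        for gapped in (sa, sb):
            i = 0
            while i < len(gapped):
                if gapped[i] == "-":
                    j = i
                    while j < len(gapped) and gapped[j] == "-":
                        j += 1
                    if i != 0 and j != len(gapped):  # internal run only
                        s -= OPEN + EXT * (j - i)
                    i = j
                else:
                    i += 1
        return s

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_alignment(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


class TestGlobalAlign:
    def test_identical(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.identity_pct == 100.0 and aln.gap_columns == 0
        assert aln.score == 20.0

    def test_single_deletion(self):
        # end gaps penalised so the single-deletion alignment is forced
        aln = global_align("ACGT", "AGT", end_gaps_free=False)
        assert aln.aligned_length == 4
        assert aln.gap_columns == 1
        assert percent_identity(aln, "all_columns") == 75.0

    def test_gap_removal_recovers_inputs(self):
        a, b = "ACGTACGTAA", "ACGTCGTA"
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_score_symmetry(self):
        rng = np.random.default_rng(2)
        a = random_dna(rng, 40)
        b = random_dna(rng, 35)
        assert global_align(a, b).score == global_align(b, a).score

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        la, lb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        a, b = random_dna(rng, la), random_dna(rng, lb)
        assert global_align(a, b).score == pytest.approx(
            oracle_best_score(a, b))

    def test_size_limit(self):
        with pytest.raises(ValueError):
            global_align("A" * 10, "A" * 10, max_length=5)


class TestPercentIdentity:
    def test_simple(self):
        aln = global_align("AAAA", "AAAT", end_gaps_free=False)
        assert percent_identity(aln, "all_columns") == 75.0

    def test_end_gap_modes(self):
        aln = Alignment("a", "b", "AAAA", "AA--", 0, 0, 4, 2)
        assert percent_identity(aln, "exclude_end_gaps") == 100.0
        assert percent_identity(aln, "all_columns") == 50.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            percent_identity(Alignment("a", "b", "", "", 0, 0, 0, 0))


class TestLocalMap:
    def test_verbatim_plant(self):
        rng = np.random.default_rng(1)
        query = random_dna(rng, 300)
        target = random_dna(rng, 1000) + query + random_dna(rng, 1000)
        (hit,) = local_map(query, target)
        assert hit.strand == "+"
        assert hit.identity_pct == 100.0
        assert (hit.target_region.start, hit.target_region.end) == (1001, 1300)
        assert (hit.query_region.start, hit.query_region.end) == (1, 300)

    def test_revcomp_plant_with_mutations(self):
        rng = np.random.default_rng(6)
        query = random_dna(rng, 400)
        planted = list(reverse_complement(query))
        n_mut = 16  # 4% substitutions
        for i in rng.choice(len(planted), size=n_mut, replace=False):
            planted[i] = rng.choice([b for b in "ACGT" if b != planted[i]])
        target = random_dna(rng, 500) + "".join(planted) + random_dna(rng, 500)
        hits = local_map(query, target)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert 95.0 <= hits[0].identity_pct <= 98.5

    def test_absent_query(self):
        rng = np.random.default_rng(9)
        assert local_map(random_dna(rng, 200), random_dna(rng, 2000)) == []

    def test_all_planted_copies_found_no_false_hits(self):
        rng = np.random.default_rng(13)
        query = random_dna(rng, 250)
        copies = []
        target_parts = []
        pos = 0
        for _ in range(4):
            gap = random_dna(rng, 400)
            target_parts.append(gap)
            pos += len(gap)
            mutated = list(query)
            for i in rng.choice(len(mutated), size=12, replace=False):
                mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
            target_parts.append("".join(mutated))
            copies.append((pos + 1, pos + len(query)))
            pos += len(query)
        target = "".join(target_parts)
        hits = local_map(query, target)
        assert len(hits) == 4
        found = sorted((h.target_region.start, h.target_region.end)
                       for h in hits)
        for (ws, we), (hs, he) in zip(copies, found):
            assert abs(ws - hs) <= 5 and abs(we - he) <= 5
        # shuffled target: no hits at default thresholds
        shuffled = "".join(rng.permutation(list(target)))
        assert local_map(query, shuffled) == []


class TestMotifFate:
    def test_conserved(self):
        s = "GG" + MOTIF + "CCGGACTT"
        aln = global_align(s, s)
        (rec,) = classify_motif_fate(aln, MOTIF)
        assert rec.category == "conserved"
        assert rec.species_a_position == rec.species_b_position == 3

    def test_substitution_creates_motif(self):
        a = "GGCC" + MOTIF + "GGCCAA"
        b = a.replace(MOTIF, MOTIF[:2] + "C" + MOTIF[3:])
        aln = global_align(a, b)
        (rec,) = classify_motif_fate(aln, MOTIF)
        assert rec.category == "a_only"
        assert rec.cause == "substitution"

    def test_insertion_splits_motif(self):
        # a carries a 6-nt insertion splitting a motif that is intact in b
        b = "GCGC" + MOTIF + "GCGCAT"
        a = "GCGC" + MOTIF[:4] + "GGCCGG" + MOTIF[4:] + "GCGCAT"
        aln = global_align(a, b)
        recs = classify_motif_fate(aln, MOTIF)
        b_only = [r for r in recs if r.category == "b_only"]
        assert len(b_only) == 1
        assert b_only[0].cause == "insertion"

    def test_totals_consistent_with_counts(self):
        rng = np.random.default_rng(21)
        from patrrkit.simulate import make_variable_region, mutate_sequence
        a, _ = make_variable_region(800, 0.07, MOTIF, 12, seed=3)
        b = mutate_sequence(a.residues, 0.1, 0.01, rng)
        aln = global_align(a.residues, b)
        recs = classify_motif_fate(aln, MOTIF)
        n_cons = sum(r.category == "conserved" for r in recs)
        n_a = sum(r.category == "a_only" for r in recs)
        n_b = sum(r.category == "b_only" for r in recs)
        assert n_cons + n_a == count_motif(a, MOTIF)[0]
        assert n_cons + n_b == count_motif(b, MOTIF)[0]
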