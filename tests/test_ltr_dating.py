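"""Insertion-dating pipeline: alignment, K2P distance, ages, recency contrast.

Independent oracles: a brute-force enumerator of all global alignments with
affine gap costs (short sequences), exact-integer Fisher enumeration, and
closed-form arithmetic for distances and ages.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroatlas import ltr_dating as ld
from retroatlas import synthetic_data as sd
from conftest import brute_force_fisher


def make_element(ltr5, ltr3, eid="e1", family="Athila",
                 domains=ld.REQUIRED_DOMAINS):
    return ld.LTRElement(element_id=eid, family=family, ltr5=ltr5, ltr3=ltr3,
                         domains_present=domains)


class TestFilterFullLength:
    def test_all_five_domains_retained(self):
        el = make_element("ACGT", "ACGT")
        assert ld.filter_full_length([el]) == [el]

    def test_missing_int_dropped(self):
        el = make_element("ACGT", "ACGT",
                         domains={"GAG", "RT", "RH", "AP"})
        assert ld.filter_full_length([el]) == []

    def test_empty_input(self):
        assert ld.filter_full_length([]) == []


def brute_force_alignment_score(a, b, scoring):
    """Best global alignment score by exhaustive enumeration of all monotone
    alignments, scoring gap runs with affine costs (open for the first gap
    of a run, extend for each further gap)."""
    best = -math.inf

    def recurse(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = scoring.match if a[i] == b[j] else scoring.mismatch
            recurse(i + 1, j + 1, score + s, "m")
        if i < len(a):
            s = scoring.gap_extend if last == "d" else scoring.gap_open
            recurse(i + 1, j, score + s, "d")
        if j < len(b):
            s = scoring.gap_extend if last == "i" else scoring.gap_open
            recurse(i, j + 1, score + s, "i")

    recurse(0, 0, 0.0, "m")
    return best


class TestAlignLtrPair:
    def test_identical_sequences_no_gaps_no_mismatches(self):
        aln = ld.align_ltr_pair(make_element("ACGTACGT", "ACGTACGT"))
        assert aln.count(ld.COL_GAP) == 0
        assert set(aln.columns) == {ld.COL_MATCH}

    def test_single_transition_column(self):
        # C->T is a transition; the other three columns match
        aln = ld.align_ltr_pair(make_element("ACGT", "ATGT"))
        assert aln.count(ld.COL_TRANSITION) == 1
        assert aln.count(ld.COL_MATCH) == 3
        assert aln.count(ld.COL_TRANSVERSION) == 0

    def test_transversion_column(self):
        aln = ld.align_ltr_pair(make_element("ACGT", "AGGT"))
        assert aln.count(ld.COL_TRANSVERSION) == 1

    def test_length_difference_gives_gap_columns(self):
        aln = ld.align_ltr_pair(make_element("AAAA", "AA"))
        assert aln.count(ld.COL_GAP) == 2
        assert aln.count(ld.COL_MATCH) == 2

    def test_ambiguous_columns(self):
        aln = ld.align_ltr_pair(make_element("ACGT", "ANGT"))
        assert aln.count(ld.COL_AMBIGUOUS) == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            make_element("", "ACGT")

    def test_optimal_score_matches_brute_force_on_all_short_pairs(self):
        """Exhaustive DP check: the aligner's score equals the brute-force
        optimum over every alignment, for a systematic sweep of 4-mers."""
        scoring = ld.AlignmentScoring()
        rng = np.random.default_rng(0)
        pairs = [("".join(x), "".join(y)) for x, y in itertools.product(
            itertools.product("ACGT", repeat=2), repeat=2)]
        # every 2-mer vs 2-mer pair, plus random 3/4-mer pairs
        for n in (3, 4):
            for _ in range(40):
                pairs.append((sd.random_sequence(n, rng),
                              sd.random_sequence(rng.integers(1, n + 1), rng)))
        for a, b in pairs:
            aln = ld.align_ltr_pair(make_element(a, b), scoring)
            assert aln.score == pytest.approx(
                brute_force_alignment_score(a, b, scoring)), (a, b)


class TestSubstitutionFrequencies:
    def test_identical_hundred_mer(self):
        aln = ld.align_ltr_pair(make_element("A" * 50 + "C" * 50,
                                             "A" * 50 + "C" * 50))
        assert ld.substitution_frequencies(aln) == (0.0, 0.0, 100)

    def test_counting(self):
        cols = ([ld.COL_MATCH] * 85 + [ld.COL_TRANSITION] * 10
                + [ld.COL_TRANSVERSION] * 5)
        aln = ld.LTRAlignment("", "", 0.0, tuple(cols))
        p, q, n = ld.substitution_frequencies(aln)
        assert (p, q, n) == (0.10, 0.05, 100)

    def test_gap_columns_excluded(self):
        cols = [ld.COL_MATCH] * 100 + [ld.COL_GAP] * 20
        aln = ld.LTRAlignment("", "", 0.0, tuple(cols))
        assert ld.substitution_frequencies(aln)[2] == 100

    def test_all_gap_alignment_rejected(self):
        aln = ld.LTRAlignment("", "", 0.0, (ld.COL_GAP,) * 4)
        with pytest.raises(ValueError, match="undefined"):
            ld.substitution_frequencies(aln)


class TestK2PDistance:
    def test_zero_frequencies_zero_distance(self):
        est = ld.k2p_distance(0.0, 0.0)
        assert est.K == 0.0 and not est.saturated

    def test_known_value(self):
        # -1/2 ln[(1 - 0.2 - 0.05) * sqrt(1 - 0.1)], evaluated symbolically
        est = ld.k2p_distance(0.10, 0.05)
        assert est.K == pytest.approx(0.17018116514034703, rel=1e-12)

    def test_saturation_boundary(self):
        est = ld.k2p_distance(0.45, 0.10)  # 1 - 2p - q = 0
        assert est.saturated and math.isnan(est.K)

    @given(p=st.floats(0.0, 0.3), q=st.floats(0.0, 0.3),
           dp=st.floats(1e-6, 0.05))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strictly_increasing_in_p_and_q(self, p, q, dp):
        if 1 - 2 * (p + dp) - (q + dp) <= 1e-9 or 1 - 2 * (q + dp) <= 1e-9:
            return
        base = ld.k2p_distance(p, q).K
        assert ld.k2p_distance(p + dp, q).K > base
        assert ld.k2p_distance(p, q + dp).K > base


class TestInsertionTime:
    def test_zero_distance_is_recent(self):
        est = ld.insertion_time(0.0)
        assert est.T == 0.0 and est.recent

    def test_boundary_age_is_old_under_strict_less(self):
        # K = 0.013 at r = 1.3e-8 -> exactly 500,000 years
        est = ld.insertion_time(0.013, r=1.3e-8, threshold_years=5e5)
        assert est.T == pytest.approx(5e5)
        assert not est.recent

    def test_doubling_rate_halves_age(self):
        for K in (0.001, 0.05, 0.2):
            assert ld.insertion_time(K, r=2.6e-8).T == pytest.approx(
                ld.insertion_time(K, r=1.3e-8).T / 2)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            ld.insertion_time(0.01, r=0.0)


class TestEstimatorConsistency:
    @pytest.mark.parametrize("k_true", [0.001, 0.02, 0.1, 0.2])
    def test_mean_estimate_recovers_true_divergence(self, k_true):
        """Across simulated 1,000 bp pairs the mean estimated K lies within
        3 SE of the true divergence."""
        n_pairs, length = 200, 1000
        age = k_true / (2 * 1.3e-8)
        els, _ = sd.simulate_ltr_pairs(
            n_pairs, length, sd.uniform_ages(age, age),
            sd.EvolutionSpec(seed=int(k_true * 1e4)))
        table = ld.date_elements(els)
        ks = table.loc[~table["saturated"], "K"]
        se = ks.std(ddof=1) / math.sqrt(len(ks))
        assert abs(ks.mean() - k_true) < 3 * max(se, 1e-6)


class TestRecencyAndFisher:
    def test_contingency_counts(self):
        mk = lambda t, thr=5e5: ld.insertion_time(2 * 1.3e-8 * t,
                                                  threshold_years=thr)
        a = [mk(1e5), mk(2e5), mk(6e5), mk(1e6)]
        b = [mk(1e5), mk(7e5), mk(8e5), mk(9e5)]
        table = ld.recency_contingency(a, b)
        assert table.as_array().tolist() == [[2, 2], [1, 3]]

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            ld.recency_contingency([], [ld.insertion_time(0.0)])

    def test_no_association_gives_p_one(self):
        assert ld.fisher_exact(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_known_table_vs_enumeration(self):
        p = ld.fisher_exact(np.array([[1, 9], [11, 3]]))
        assert p == pytest.approx(brute_force_fisher(1, 9, 11, 3), rel=1e-9)
        assert p == pytest.approx(0.00276, abs=2e-5)

    def test_symmetry_under_row_swap_and_transpose(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            p = ld.fisher_exact(t)
            assert ld.fisher_exact(t[::-1]) == pytest.approx(p, rel=1e-9)
            assert ld.fisher_exact(t.T) == pytest.approx(p, rel=1e-9)

    def test_matches_scipy_on_random_tables(self):
        """Cross-check against an independent implementation of the same
        two-sided convention."""
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(10)
        for _ in range(100):
            t = rng.integers(0, 40, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert ld.fisher_exact(t) == pytest.approx(
                scipy_fisher(t)[1], rel=1e-7)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ld.fisher_exact(np.array([[1, -1], [2, 3]]))


class TestSummaries:
    def test_family_fold_ratio_on_printed_counts(self):
        """Athila copy numbers 6,117 vs 241 give a fold ratio rounding to 25."""
        summary = ld.family_copy_summary({"Athila": 6117}, {"Athila": 241})
        assert round(float(summary["fold_ratio"].iloc[0])) == 25

    def test_family_absent_from_both_omitted(self):
        summary = ld.family_copy_summary({"Athila": 3, "Tekay": 0},
                                         {"Athila": 1, "Tekay": 0})
        assert list(summary["family"]) == ["Athila"]

    def test_single_genome_fractions_sum_to_one(self):
        els = [make_element("ACGT", "ACGT", eid=f"e{i}", family=f)
               for i, f in enumerate(["Ale", "Ale", "SIRE", "Tork"])]
        summary = ld.family_copy_summary(els, {})
        assert summary["fraction_a"].sum() == pytest.approx(1.0)

    def test_zero_count_in_b_flagged(self):
        summary = ld.family_copy_summary({"Ale": 4}, {"Tekay": 2})
        ale = summary.set_index("family").loc["Ale"]
        assert math.isnan(ale["fold_ratio"])

    def test_cumulative_curve_step_function(self):
        curve = ld.cumulative_age_curve([1e6] * 5, [0.0, 5e5, 1e6, 2e6])
        assert curve.tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_cumulative_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(0, 3e6, size=200)
        grid = np.linspace(0, 3e6, 50)
        curve = ld.cumulative_age_curve(ages, grid)
        assert (np.diff(curve) >= 0).all()
        assert curve[-1] == 1.0

    def test_cumulative_curve_uniform_ages_track_cdf(self):
        """Uniform ages on [0, 2 My]: the curve stays within 3 SE of the
        uniform CDF at every grid point."""
        n = 2000
        rng = np.random.default_rng(3)
        ages = rng.uniform(0, 2e6, size=n)
        grid = np.linspace(1e5, 1.9e6, 10)
        curve = ld.cumulative_age_curve(ages, grid)
        expected = grid / 2e6
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(curve - expected) < 3 * se).all()

    def test_empty_times_rejected(self):
        with pytest.raises(ValueError):
            ld.cumulative_age_curve([], [0.0, 1.0])


class TestRepeatRenormalize:
    def _table(self, rows, total):
        import pandas as pd

        return ld.RepeatClusterTable(
            clusters=pd.DataFrame(rows, columns=["cluster", "annotation",
                                                 "reads", "organelle"]),
            total_reads=total)

    def test_no_organelle_unchanged(self):
        t = self._table([("c1", "Athila", 100, False),
                         ("c2", "satellite", 50, False)], 1000)
        frac = ld.repeat_fraction_renormalize(t)
        assert frac["Athila"] == pytest.approx(0.1)

    def test_corrected_fraction(self):
        # 200 of 1,000 reads are organelle: cluster X (80 reads) -> 0.10
        t = self._table([("c1", "X", 80, False),
                         ("c2", "plastid", 200, True)], 1000)
        frac = ld.repeat_fraction_renormalize(t)
        assert frac["X"] == pytest.approx(0.10)
        assert "plastid" not in frac.index

    def test_fractions_conserved(self):
        t = self._table([("c1", "A", 300, False), ("c2", "B", 200, False),
                         ("c3", "plastid", 100, True)], 1000)
        assert ld.repeat_fraction_renormalize(t).sum() <= 1.0

    def test_all_organelle_rejected(self):
        t = self._table([("c1", "plastid", 1000, True)], 1000)
        with pytest.raises(ValueError):
            ld.repeat_fraction_renormalize(t)


class TestPipelineDeterminism:
    def test_same_inputs_same_summary(self, small_ltr_library):
        from retroatlas import io

        lib = small_ltr_library
        elements = io.ltr_elements_from_gff(lib.features,
                                            {lib.contig_id: lib.genome})
        a = ld.date_elements(elements)
        b = ld.date_elements(elements)
        assert a.to_csv() == b.to_csv()
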