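import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscore import (
    AnnotationSet,
    MirnaAnnotation,
    ScoreWeights,
    compute_score,
    median_expression,
    precursor_correlation,
    scale_components,
    score_all,
)
from mirscore.scoring import DEFAULT_WEIGHTS

from conftest import spearman_bruteforce


def annotation_for(mimats, precursors=None):
    records = {
        name: MirnaAnnotation(
            name, number, (precursors[name],) if precursors else ()
        )
        for name, number in mimats.items()
    }
    return AnnotationSet(records=records)


class TestMedianExpression:
    @pytest.mark.parametrize(
        "row,expected",
        [([1.0, 2.0, 3.0], 2.0), ([1.0, 3.0], 2.0), ([7.0], 7.0)],
    )
    def test_median_conventions(self, row, expected):
        matrix = pd.DataFrame([row], index=["mir-a"],
                              columns=[f"s{i}" for i in range(len(row))])
        assert median_expression(matrix, "mir-a") == expected

    def test_unknown_feature(self, tiny_matrix):
        with pytest.raises(KeyError):
            median_expression(tiny_matrix, "mir-z")


class TestPrecursorCorrelation:
    def test_perfect_monotone_agreement(self):
        corr = precursor_correlation([1, 2, 3, 4, 5], [[10, 20, 30, 40, 50]])
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_perfect_reversal(self):
        corr = precursor_correlation([1, 2, 3, 4, 5], [[50, 40, 30, 20, 10]])
        assert corr == pytest.approx(-1.0, abs=1e-12)

    def test_multiple_precursors_take_maximum(self):
        x = [1, 2, 3, 4, 5]
        weak = [2, 1, 4, 3, 5]     # positive but imperfect
        strong = [1, 2, 3, 4, 5]
        best = precursor_correlation(x, [weak, strong])
        assert best == pytest.approx(1.0, abs=1e-12)
        assert best >= precursor_correlation(x, [weak])

    def test_below_min_samples_is_absent(self):
        assert precursor_correlation([1, 2, 3], [[1, 2, 3]]) is None
        assert precursor_correlation([1, 2, 3], [[1, 2, 3]], min_samples=3) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            precursor_correlation([1, 2, 3, 4, 5], [[1, 2, 3]])

    @given(
        st.lists(st.floats(0, 100), min_size=5, max_size=20),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_rank_based_bruteforce(self, xs, rnd):
        ys = list(xs)
        rnd.shuffle(ys)
        if len(set(xs)) < 2:
            return  # constant vectors: correlation undefined
        got = precursor_correlation(xs, [ys])
        assert got == pytest.approx(spearman_bruteforce(xs, ys), abs=1e-12)


class TestScaleComponents:
    def test_maximum_median_gives_a_one(self):
        a, _, _ = scale_components(7.0, 7.0, 10, 100, None)
        assert a == 1.0

    def test_boundary_and_neutral_midpoint(self):
        a, b, c = scale_components(3.5, 7.0, 100, 100, 0.0)
        assert b == 0.0 and c == 0.5 and a == 0.5

    def test_correlation_endpoints(self):
        assert scale_components(1, 1, 1, 2, 1.0)[2] == 1.0
        assert scale_components(1, 1, 1, 2, -1.0)[2] == 0.0

    def test_absent_correlation_maps_to_neutral(self):
        assert scale_components(1, 1, 1, 2, None)[2] == 0.5

    def test_mimat_above_n_max_clips_b_to_zero(self):
        assert scale_components(1, 1, 500, 100, None)[1] == 0.0

    @pytest.mark.parametrize("m_max,n_max", [(0, 10), (-1, 10), (1, 0)])
    def test_degenerate_maxima_rejected(self, m_max, n_max):
        with pytest.raises(ValueError):
            scale_components(1, m_max, 1, n_max, None)


class TestComputeScore:
    def test_bounds_attained(self):
        assert compute_score((1.0, 1.0, 1.0)) == 1.0
        assert compute_score((0.0, 0.0, 0.0)) == 0.0

    def test_hand_evaluated_combination(self):
        assert compute_score((1.0, 0.0, 0.5), ScoreWeights(0.5, 0.3, 0.2)) == pytest.approx(0.6)

    def test_component_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="component"):
            compute_score((1.2, 0.0, 0.0))

    def test_weights_renormalized(self):
        w = ScoreWeights(0.5, 0.3, 0.0)
        assert w.as_tuple() == pytest.approx((0.625, 0.375, 0.0))
        with pytest.raises(ValueError):
            ScoreWeights(0.0, 0.0, 0.0)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_always_within_unit_interval(self, a, b, c, wa, wb, wc):
        score = compute_score((a, b, c), ScoreWeights(wa, wb, wc))
        assert -1e-9 <= score <= 1 + 1e-9


def straight_line_scores(matrix, annotation, precursor_matrix, weights):
    """Independent re-derivation of the scoring definition, row by row.

    Deliberately naive: explicit medians, rank correlation via the
    brute-force helper, and scalar arithmetic — no shared code with score_all
    beyond the annotation container.
    """
    medians = {f: float(np.median(matrix.loc[f])) for f in matrix.index
               if f in annotation}
    m_max = max(medians.values())
    n_max = annotation.n_max
    scores = {}
    for name, m in medians.items():
        record = annotation[name]
        a = m / m_max
        b = max(0.0, 1.0 - record.mimat_number / n_max)
        c_scaled = 0.5
        if precursor_matrix is not None and record.precursor_names:
            best = None
            for precursor in record.precursor_names:
                if precursor not in precursor_matrix.index:
                    continue
                if matrix.shape[1] < 5:
                    continue
                rho = spearman_bruteforce(
                    matrix.loc[name].to_numpy(),
                    precursor_matrix.loc[precursor].to_numpy(),
                )
                if not np.isnan(rho) and (best is None or rho > best):
                    best = rho
            if best is not None:
                c_scaled = (best + 1) / 2
        scores[name] = weights.w_a * a + weights.w_b * b + weights.w_c * c_scaled
    return scores


def random_problem(rng):
    n_mirna = rng.integers(1, 11)
    n_samples = rng.integers(1, 11)
    names = [f"mir-{i}" for i in range(n_mirna)]
    precursors = {name: f"pre-{name}" for name in names}
    mimats = {name: int(rng.integers(1, 35000)) for name in names}
    matrix = pd.DataFrame(
        rng.uniform(0, 14, size=(n_mirna, n_samples)),
        index=names,
        columns=[f"s{j}" for j in range(n_samples)],
    )
    precursor_matrix = pd.DataFrame(
        rng.uniform(0, 14, size=(n_mirna, n_samples)),
        index=[precursors[n] for n in names],
        columns=matrix.columns,
    )
    weights = ScoreWeights(*rng.dirichlet([1, 1, 1]))
    return matrix, annotation_for(mimats, precursors), precursor_matrix, weights


class TestScoreAllOracle:
    def test_matches_straight_line_recomputation_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            matrix, annotation, precursor_matrix, weights = random_problem(rng)
            table = score_all(matrix, annotation, precursor_matrix, weights)
            expected = straight_line_scores(matrix, annotation, precursor_matrix, weights)
            assert len(table) == len(expected)
            for name, value in expected.items():
                assert table.frame.loc[name, "score"] == pytest.approx(value, abs=1e-12)


class TestScoreAllBehavior:
    def test_single_mirna_is_its_own_maximum(self):
        matrix = pd.DataFrame([[0.3, 0.4, 0.5]], index=["mir-a"],
                              columns=["s1", "s2", "s3"])
        table = score_all(matrix, annotation_for({"mir-a": 7}))
        assert table.frame.loc["mir-a", "A"] == 1.0

    def test_lower_mimat_outranks_on_identical_expression(self):
        matrix = pd.DataFrame(
            [[5.0, 6.0, 7.0], [5.0, 6.0, 7.0]],
            index=["early", "late"],
            columns=["s1", "s2", "s3"],
        )
        table = score_all(matrix, annotation_for({"early": 100, "late": 30000}))
        assert table.frame.loc["early", "score"] > table.frame.loc["late", "score"]
        assert list(table.frame.index)[0] == "early"

    def test_planted_truth_fully_separated_when_only_mimat_and_corr_differ(self):
        # equal medians by construction: separation must come from B and C
        rng = np.random.default_rng(7)
        n, s = 10, 20
        names = [f"true-{i}" for i in range(n)] + [f"false-{i}" for i in range(n)]
        rows = 8.0 + rng.standard_normal((2 * n, s))
        rows -= np.median(rows, axis=1, keepdims=True) - 8.0  # equal medians
        matrix = pd.DataFrame(rows, index=names, columns=[f"s{j}" for j in range(s)])
        mimats = {name: (50 + i if name.startswith("true") else 30000 + i)
                  for i, name in enumerate(names)}
        precursors = {name: f"pre-{name}" for name in names}
        pre_rows = []
        for name in names:
            if name.startswith("true"):
                pre_rows.append(matrix.loc[name].to_numpy() * 0.5 + 1.0)  # rho = 1
            else:
                pre_rows.append(rng.uniform(0, 10, size=s))
        precursor_matrix = pd.DataFrame(
            pre_rows, index=[precursors[n] for n in names], columns=matrix.columns
        )
        table = score_all(matrix, annotation_for(mimats, precursors), precursor_matrix)
        truth_scores = table.frame.loc[[n for n in names if n.startswith("true")], "score"]
        false_scores = table.frame.loc[[n for n in names if n.startswith("false")], "score"]
        assert truth_scores.min() > false_scores.max()

    def test_unannotated_features_reported_not_dropped(self, tiny_matrix):
        table = score_all(tiny_matrix, annotation_for({"mir-a": 10}))
        assert table.unannotated == ("mir-b",)
        assert list(table.frame.index) == ["mir-a"]

    def test_empty_intersection_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="overlap"):
            score_all(tiny_matrix, annotation_for({"mir-z": 10}))

    def test_sample_set_mismatch_rejected(self, tiny_matrix):
        precursor = tiny_matrix.rename(columns={"s3": "s9"})
        precursor.index = ["pre-mir-a", "pre-mir-b"]
        with pytest.raises(ValueError, match="sample"):
            score_all(
                tiny_matrix,
                annotation_for({"mir-a": 5, "mir-b": 9},
                               {"mir-a": "pre-mir-a", "mir-b": "pre-mir-b"}),
                precursor,
            )

    def test_negative_values_rejected_unless_shifted(self):
        matrix = pd.DataFrame([[-1.0, 2.0, 3.0]], index=["mir-a"],
                              columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="negative"):
            score_all(matrix, annotation_for({"mir-a": 5}))
        table = score_all(matrix, annotation_for({"mir-a": 5}), negative="shift")
        assert table.frame.loc["mir-a", "median"] == 3.0  # medians on shifted scale


class TestScoreProperties:
    """Invariants of the scoring map on the default synthetic study."""

    def test_scores_within_unit_interval(self, default_scores):
        scores = default_scores.frame["score"]
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_monotone_in_median_mimat_and_correlation(self):
        # holding everything else fixed, perturb one signal at a time
        base = dict(m=4.0, m_max=10.0, N=500, n_max=1000, c=0.3)
        w = DEFAULT_WEIGHTS

        def s(**kw):
            args = {**base, **kw}
            return compute_score(
                scale_components(args["m"], args["m_max"], args["N"],
                                 args["n_max"], args["c"]), w)

        for lo, hi in [(1.0, 2.0), (4.0, 9.0)]:
            assert s(m=lo) <= s(m=hi)
        for lo, hi in [(10, 100), (500, 999)]:
            assert s(N=lo) >= s(N=hi)
        for lo, hi in [(-0.9, 0.0), (0.2, 0.9)]:
            assert s(c=lo) <= s(c=hi)

    def test_sample_permutation_invariance(self, default_dataset):
        d = default_dataset
        rng = np.random.default_rng(3)
        perm = rng.permutation(d.mirna_matrix.columns.to_numpy())
        permuted = score_all(
            d.mirna_matrix[perm], d.annotation, d.precursor_matrix[perm]
        )
        reference = score_all(d.mirna_matrix, d.annotation, d.precursor_matrix)
        pd.testing.assert_series_equal(
            permuted.frame["score"], reference.frame["score"]
        )

    def test_weight_degeneracy_median_only_ranking(self, default_dataset):
        d = default_dataset
        table = score_all(d.mirna_matrix, d.annotation, d.precursor_matrix,
                          ScoreWeights(1.0, 0.0, 0.0))
        by_median = d.mirna_matrix.median(axis=1).sort_values(ascending=False)
        assert list(table.frame.index) == list(by_median.index)
        np.testing.assert_allclose(
            table.frame["score"].to_numpy(),
            (by_median / by_median.max()).to_numpy(),
        )

    def test_weight_degeneracy_constant_c_without_precursors(self, default_dataset):
        d = default_dataset
        table = score_all(d.mirna_matrix, d.annotation, None,
                          ScoreWeights(0.0, 0.0, 1.0))
        assert (table.frame["score"] == 0.5).all()

    def test_zero_correlation_weight_ignores_precursor_matrix(self, default_dataset):
        d = default_dataset
        with_pre = score_all(d.mirna_matrix, d.annotation, d.precursor_matrix,
                             missing_corr="drop-weight")
        without_pre = score_all(d.mirna_matrix, d.annotation, None,
                                missing_corr="drop-weight")
        pd.testing.assert_series_equal(
            with_pre.frame["score"], without_pre.frame["score"]
        )
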