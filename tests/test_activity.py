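import numpy as np
import pytest

from ictair import (
    ChannelMode,
    ExpressionMatrix,
    GeneSet,
    compute_iras,
    make_weight_vector,
    normalize_expression,
    preliminary_score,
    sample_curves,
    score_collection,
)

from .conftest import random_matrix


def brute_force_score(weights, column):
    """Independent oracle: scan every prefix of the descending ordering."""
    order = sorted(range(len(column)), key=lambda j: (-column[j], j))
    a = np.abs(np.asarray(column, dtype=float))[order]
    w = np.asarray(weights, dtype=float)[order]
    fg_inc = a * w if (a * w).sum() > 0 else w
    bg_inc = a * (1 - w) if (a * (1 - w)).sum() > 0 else (1 - w)
    f = np.cumsum(fg_inc) / fg_inc.sum()
    b = np.cumsum(bg_inc) / bg_inc.sum()
    best = 0.0
    for k in range(len(column)):
        if abs(f[k] - b[k]) > abs(best):
            best = f[k] - b[k]
    return best


class TestNormalize:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0]),
            ([1.0, 2.0, 3.0, 10.0], [-1.5, -0.5, 0.5, 7.5]),  # even count: mid-mean
        ],
    )
    def test_one_channel_median_centering(self, row, expected):
        m = ExpressionMatrix(
            ("A",), tuple(f"s{i}" for i in range(len(row))),
            np.array([row]), ChannelMode.one_channel,
        )
        out = normalize_expression(m)
        np.testing.assert_allclose(out.values[0], expected)
        assert out.channel_mode is ChannelMode.pre_normalized

    @pytest.mark.parametrize(
        "mode", [ChannelMode.two_channel, ChannelMode.pre_normalized]
    )
    def test_relative_modes_pass_through(self, mode):
        m = ExpressionMatrix(("A",), ("s1", "s2"), np.array([[0.5, -0.2]]), mode)
        out = normalize_expression(m)
        np.testing.assert_array_equal(out.values, m.values)
        assert out.channel_mode is ChannelMode.pre_normalized


class TestWeightVector:
    def test_membership_encoding(self):
        m = random_matrix(4, 2, 0)
        m = ExpressionMatrix(("A", "B", "C", "D"), m.sample_ids, m.values, m.channel_mode)
        w = make_weight_vector(GeneSet("R", "d", ("A", "C")), m)
        np.testing.assert_array_equal(w.values, [1, 0, 1, 0])
        assert w.n_targets_effective == 2

    def test_absent_members_dropped_with_warning(self, caplog):
        m = random_matrix(2, 2, 0)
        m = ExpressionMatrix(("A", "B"), m.sample_ids, m.values, m.channel_mode)
        with caplog.at_level("WARNING"):
            w = make_weight_vector(GeneSet("R", "d", ("A", "X")), m)
        np.testing.assert_array_equal(w.values, [1, 0])
        assert w.dropped == ("X",)
        assert "X" in caplog.text

    def test_no_effective_targets_is_error(self):
        m = random_matrix(3, 2, 0)
        with pytest.raises(ValueError, match="no listed gene"):
            make_weight_vector(GeneSet("R", "d", ("X", "Y")), m)

    def test_all_genes_targets_is_error(self):
        m = random_matrix(3, 2, 0)
        with pytest.raises(ValueError, match="all matrix genes"):
            make_weight_vector(GeneSet("R", "d", m.gene_ids), m)


class TestCurves:
    def test_worked_six_gene_example(self, six_gene_matrix, top_two_targets):
        w = make_weight_vector(top_two_targets, six_gene_matrix)
        c = sample_curves(w, six_gene_matrix.values[:, 0])
        np.testing.assert_allclose(c.foreground, [0.6, 1, 1, 1, 1, 1], atol=1e-12)
        np.testing.assert_allclose(
            c.background, [0, 0, 1 / 7, 2 / 7, 4 / 7, 1], atol=1e-12
        )
        assert preliminary_score(c) == pytest.approx(1.0, abs=1e-12)

    def test_curves_non_decreasing_and_end_at_one(self):
        m = random_matrix(30, 5, 1, round_to=1)  # rounding induces ties/zeros
        gs = GeneSet("R", "d", tuple(m.gene_ids[i] for i in (0, 3, 7, 8, 20)))
        w = make_weight_vector(gs, m)
        for i in range(m.n_samples):
            c = sample_curves(w, m.values[:, i])
            for curve in (c.foreground, c.background):
                assert (np.diff(curve) >= -1e-12).all()
                assert curve[-1] == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_expression_uses_index_order(self):
        m = ExpressionMatrix(
            ("A", "B", "C", "D"), ("s1",), np.full((4, 1), 2.0), "pre_normalized"
        )
        w = make_weight_vector(GeneSet("R", "d", ("B", "D")), m)
        c = sample_curves(w, m.values[:, 0])
        np.testing.assert_array_equal(c.order, [0, 1, 2, 3])
        np.testing.assert_allclose(c.foreground, [0, 0.5, 0.5, 1.0])

    def test_zero_magnitude_class_falls_back_to_uniform_steps(self):
        m = ExpressionMatrix(
            ("A", "B", "C"), ("s1",), np.array([[0.0], [0.0], [1.0]]), "pre_normalized"
        )
        w = make_weight_vector(GeneSet("R", "d", ("A", "B")), m)
        c = sample_curves(w, m.values[:, 0])
        np.testing.assert_allclose(c.foreground, [0, 0.5, 1.0])

    def test_single_top_target_jumps_to_one(self, six_gene_matrix):
        w = make_weight_vector(GeneSet("R", "d", ("g1",)), six_gene_matrix)
        c = sample_curves(w, six_gene_matrix.values[:, 0])
        assert c.foreground[0] == pytest.approx(1.0)

    def test_uniform_weighting_ignores_magnitudes(self, six_gene_matrix, top_two_targets):
        w = make_weight_vector(top_two_targets, six_gene_matrix)
        c = sample_curves(w, six_gene_matrix.values[:, 0], weighting="uniform")
        np.testing.assert_allclose(c.foreground, [0.5, 1, 1, 1, 1, 1])
        np.testing.assert_allclose(c.background, [0, 0, 0.25, 0.5, 0.75, 1.0])


class TestPreliminaryScore:
    def test_mirror_example_is_minus_one(self, six_gene_matrix):
        w = make_weight_vector(GeneSet("R", "d", ("g5", "g6")), six_gene_matrix)
        c = sample_curves(w, six_gene_matrix.values[:, 0])
        assert preliminary_score(c) == pytest.approx(-1.0, abs=1e-12)

    def test_identical_curves_score_zero(self):
        from ictair.activity import CurvePair

        f = np.array([0.25, 0.5, 0.75, 1.0])
        c = CurvePair(foreground=f, background=f.copy(), order=np.arange(4))
        assert preliminary_score(c) == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(300):
            n = 10
            col = np.round(rng.standard_normal(n), 2)
            k = int(rng.integers(1, n))
            weights = np.zeros(n, dtype=np.int8)
            weights[rng.choice(n, k, replace=False)] = 1
            m = ExpressionMatrix(
                tuple(f"g{i}" for i in range(n)), ("s1",),
                col[:, None], "pre_normalized",
            )
            gs = GeneSet("R", "d", tuple(f"g{i}" for i in np.flatnonzero(weights)))
            w = make_weight_vector(gs, m)
            got = preliminary_score(sample_curves(w, col))
            assert got == pytest.approx(brute_force_score(weights, col), abs=1e-12)

    def test_antisymmetry_on_tie_free_columns(self):
        rng = np.random.default_rng(9)
        n = 25
        for _ in range(50):
            col = rng.standard_normal(n)
            weights = np.zeros(n, dtype=np.int8)
            weights[rng.choice(n, 6, replace=False)] = 1
            m = ExpressionMatrix(
                tuple(f"g{i}" for i in range(n)), ("s1",), col[:, None], "pre_normalized"
            )
            gs = GeneSet("R", "d", tuple(f"g{i}" for i in np.flatnonzero(weights)))
            w = make_weight_vector(gs, m)
            plus = preliminary_score(sample_curves(w, col))
            minus = preliminary_score(sample_curves(w, -col))
            # exact in real arithmetic; the reversed ordering accumulates
            # the same sums in a different order, so allow rounding only
            assert minus == pytest.approx(-plus, abs=1e-12)


class TestIras:
    def test_observed_scores_match_per_column_reference(self):
        m = random_matrix(40, 6, 13, round_to=1)
        gs = GeneSet("R", "d", tuple(m.gene_ids[i] for i in range(0, 12, 2)))
        w = make_weight_vector(gs, m)
        prof = compute_iras(gs, m, n_permutations=10, seed=0)
        for i in range(m.n_samples):
            ref = preliminary_score(sample_curves(w, m.values[:, i]))
            assert prof.preliminary[i] == pytest.approx(ref, abs=1e-12)
        np.testing.assert_allclose(
            prof.scores, prof.preliminary / prof.null_mean_abs, atol=1e-15
        )

    def test_determinism_across_runs(self):
        m = random_matrix(5, 2, 21)
        gs = GeneSet("R", "d", ("g0", "g3"))
        a = compute_iras(gs, m, n_permutations=50, seed=7)
        b = compute_iras(gs, m, n_permutations=50, seed=7)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.null_mean_abs, b.null_mean_abs)

    def test_sign_convention_top_vs_bottom(self):
        # sample 1: targets are the top-3 expressed; sample 2: the bottom-3
        values = np.array(
            [[5.0, -5.0], [4.0, -4.0], [3.0, -3.0],
             [-1.0, 1.0], [-2.0, 2.0], [-3.0, 3.0], [0.5, -0.5], [-0.5, 0.5]]
        )
        m = ExpressionMatrix(
            tuple(f"g{i}" for i in range(8)), ("up", "down"), values, "pre_normalized"
        )
        gs = GeneSet("R", "d", ("g0", "g1", "g2"))
        prof = compute_iras(gs, m, n_permutations=100, seed=3)
        assert prof.scores[0] > 0
        assert prof.scores[1] < 0

    def test_sample_exchangeability(self):
        m = random_matrix(30, 8, 17)
        gs = GeneSet("R", "d", tuple(m.gene_ids[i] for i in (1, 4, 9, 16)))
        prof = compute_iras(gs, m, n_permutations=40, seed=2)
        perm = np.array([3, 1, 7, 0, 5, 2, 6, 4])
        m2 = ExpressionMatrix(
            m.gene_ids, tuple(m.sample_ids[i] for i in perm),
            m.values[:, perm], m.channel_mode,
        )
        prof2 = compute_iras(gs, m2, n_permutations=40, seed=2)
        np.testing.assert_allclose(prof2.scores, prof.scores[perm], atol=1e-12)

    def test_unnormalized_matrix_rejected(self):
        m = random_matrix(5, 2, 0)
        m = ExpressionMatrix(m.gene_ids, m.sample_ids, m.values, ChannelMode.one_channel)
        with pytest.raises(ValueError, match="normalize"):
            compute_iras(GeneSet("R", "d", ("g0",)), m, n_permutations=5, seed=0)

    def test_bad_permutation_count_rejected(self):
        m = random_matrix(5, 2, 0)
        with pytest.raises(ValueError):
            compute_iras(GeneSet("R", "d", ("g0",)), m, n_permutations=0, seed=0)


class TestScoreCollection:
    def test_rows_independent_of_batch_composition(self):
        m = random_matrix(50, 4, 29)
        sets = [
            GeneSet("R1", "d", tuple(m.gene_ids[:5])),
            GeneSet("R2", "d", tuple(m.gene_ids[10:18])),
        ]
        batch = score_collection(sets, m, n_permutations=30, seed=6)
        solo = score_collection([sets[1]], m, n_permutations=30, seed=6)
        np.testing.assert_array_equal(batch.scores[1], solo.scores[0])
        assert batch.regulator_names == ("R1", "R2")
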