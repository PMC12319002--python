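import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delphiahp.ahp import (
    AhpError,
    ConsistencyGateError,
    JudgmentMatrix,
    SaatyMapping,
    build_matrix,
    calibrate_mapping,
    column_mean_weights,
    combine_weights,
    consistency,
    full_ahp,
    geometric_mean_weights,
    principal_weights,
)


def eig_oracle(a):
    """Independent dense eigen-solver route for the principal eigenvector."""
    vals, vecs = np.linalg.eig(np.asarray(a, dtype=float))
    k = np.argmax(vals.real)
    v = np.abs(vecs[:, k].real)
    return v / v.sum(), float(vals[k].real)


def random_reciprocal(rng, n):
    a = np.ones((n, n))
    scale_values = np.array([1/9, 1/7, 1/5, 1/3, 1/2, 1, 2, 3, 5, 7, 9])
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = rng.choice(scale_values)
            a[j, i] = 1.0 / a[i, j]
    return a


class TestSaatyMapping:
    @pytest.mark.parametrize(
        "diff, expected",
        [
            (0.0, 1),
            (0.07, 2),
            (0.13, 2),
            (0.15, 2),
            (0.20, 3),
            (0.33, 3),
            (0.40, 4),
            (0.60, 5),
            (0.67, 5),
            (0.80, 6),
            (0.93, 7),
            (2.5, 7),
        ],
    )
    def test_default_bins(self, diff, expected):
        assert SaatyMapping().scale(diff) == expected

    def test_sign_ignored(self):
        assert SaatyMapping().scale(-0.6) == 5

    def test_decreasing_bounds_rejected(self):
        with pytest.raises(AhpError, match="increasing"):
            SaatyMapping(((0.0, 1), (0.5, 3), (0.4, 4)))

    def test_decreasing_scales_rejected(self):
        with pytest.raises(AhpError, match="non-decreasing"):
            SaatyMapping(((0.0, 1), (0.5, 3), (0.9, 2)))

    def test_zero_must_map_to_one(self):
        with pytest.raises(AhpError, match="scale 1"):
            SaatyMapping(((0.0, 2), (math.inf, 3)))

    def test_from_config(self):
        m = SaatyMapping.from_config(
            [{"upper": 0.0, "scale": 1}, {"upper": None, "scale": 9}]
        )
        assert m.scale(0.01) == 9


class TestBuildMatrix:
    def test_primary_matrix(self):
        m = build_matrix({"1": 5.00, "2": 5.00, "3": 4.33})
        expected = np.array([[1, 1, 5], [1, 1, 5], [0.2, 0.2, 1]])
        np.testing.assert_allclose(m.values, expected)

    def test_secondary_matrix(self):
        m = build_matrix({"1.1": 5.00, "1.2": 4.87, "1.3": 4.80})
        expected = np.array([[1, 2, 3], [0.5, 1, 2], [1 / 3, 0.5, 1]])
        np.testing.assert_allclose(m.values, expected)

    def test_single_item(self):
        m = build_matrix({"x": 4.2})
        np.testing.assert_allclose(m.values, [[1.0]])

    def test_empty_rejected(self):
        with pytest.raises(AhpError, match="empty"):
            build_matrix({})

    def test_non_finite_rejected(self):
        with pytest.raises(AhpError, match="finite"):
            build_matrix({"a": float("nan"), "b": 4.0})

    @given(
        means=st.lists(
            st.floats(1.0, 5.0, allow_nan=False), min_size=2, max_size=6
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_reciprocity_preserved(self, means):
        m = build_matrix({f"i{k}": v for k, v in enumerate(means)})
        v = m.values
        assert np.all(v > 0)
        np.testing.assert_allclose(v * v.T, 1.0, atol=1e-9)
        np.testing.assert_allclose(np.diag(v), 1.0)


class TestPrincipalWeights:
    def test_primary_weights(self):
        w, _ = principal_weights(build_matrix({"1": 5.00, "2": 5.00, "3": 4.33}))
        np.testing.assert_allclose(np.round(w, 4), [0.4545, 0.4545, 0.0909])

    def test_two_by_two_closed_form(self):
        w, lam = principal_weights(np.array([[1, 2], [0.5, 1]]))
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)
        assert lam == pytest.approx(2.0)

    def test_health_literacy_children(self):
        w, _ = principal_weights(
            build_matrix({"1.1": 5.00, "1.2": 4.87, "1.3": 4.80})
        )
        np.testing.assert_allclose(np.round(w, 4), [0.5396, 0.2970, 0.1634])

    def test_agrees_with_eigen_oracle(self):
        rng = np.random.default_rng(21)
        for n in range(2, 10):
            for _ in range(4):
                a = random_reciprocal(rng, n)
                w, lam = principal_weights(a)
                w_or, lam_or = eig_oracle(a)
                np.testing.assert_allclose(w, w_or, atol=1e-9)
                assert lam == pytest.approx(lam_or, abs=1e-9)
                assert lam >= n - 1e-9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        a = random_reciprocal(rng, 5)
        w, _ = principal_weights(a)
        perm = rng.permutation(5)
        wp, _ = principal_weights(a[np.ix_(perm, perm)])
        np.testing.assert_allclose(wp, w[perm], atol=1e-10)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(8)
        a = random_reciprocal(rng, 6)
        w, _ = principal_weights(a)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_consistent_matrix_matches_geometric_mean(self):
        # a_ik = a_ij * a_jk built from a weight vector
        v = np.array([0.5, 0.3, 0.15, 0.05])
        a = v[:, None] / v[None, :]
        w, _ = principal_weights(a)
        np.testing.assert_allclose(w, geometric_mean_weights(a), atol=1e-9)
        np.testing.assert_allclose(w, v, atol=1e-9)


class TestConsistency:
    def test_reference_cr_0089(self):
        m = build_matrix({"1.1": 5.00, "1.2": 4.87, "1.3": 4.80})
        assert round(consistency(m).cr, 4) == 0.0089

    def test_reference_cr_0176(self):
        m = JudgmentMatrix(
            ("a", "b", "c"),
            np.array([[1, 2, 4], [0.5, 1, 3], [0.25, 1 / 3, 1]]),
        )
        assert round(consistency(m).cr, 4) == 0.0176

    def test_two_by_two_defined_zero(self):
        res = consistency(np.array([[1, 7], [1 / 7, 1]]))
        assert res.cr == 0.0
        assert res.passed

    def test_exact_eigen_method_available(self):
        m = build_matrix({"1.1": 5.00, "1.2": 4.87, "1.3": 4.80})
        res = consistency(m, lambda_method="eigen")
        _, lam = eig_oracle(m.values)
        assert res.lambda_max == pytest.approx(lam, abs=1e-9)
        assert round(res.cr, 4) == 0.0088  # exact eigenvalue differs in 4th dp

    def test_consistent_matrix_cr_zero_both_methods(self):
        v = np.array([0.6, 0.25, 0.15])
        a = v[:, None] / v[None, :]
        for method in ("column_mean", "eigen"):
            assert consistency(a, lambda_method=method).cr == pytest.approx(
                0.0, abs=1e-9
            )

    def test_explicit_lambda_used(self):
        res = consistency(np.ones((3, 3)), lambda_max=3.104)
        assert res.cr == pytest.approx((0.104 / 2) / 0.52)

    def test_missing_ri_order(self):
        a = np.ones((4, 4))
        with pytest.raises(AhpError, match="random index"):
            consistency(a, random_index={3: 0.52})

    def test_column_mean_lambda_at_least_n(self):
        rng = np.random.default_rng(13)
        for n in (3, 4, 5):
            for _ in range(10):
                _, lam = column_mean_weights(random_reciprocal(rng, n))
                assert lam >= n - 1e-9


class TestCombineWeights:
    def test_local_times_parent(self, final_h, ref_means):
        report = full_ahp(final_h, ref_means)
        w = report.weights
        assert round(w.combination["1.1"], 4) == pytest.approx(
            round(0.4545454545 * w.local["1.1"], 4)
        )
        assert round(w.combination["1.1"], 4) == 0.2453

    def test_single_child_chain_inherits_parent(self, final_h, ref_means):
        w = full_ahp(final_h, ref_means).weights
        assert w.local["1.2.1"] == pytest.approx(1.0)
        assert w.combination["1.2.1"] == pytest.approx(w.combination["1.2"])
        assert round(w.combination["1.2.1"], 4) == 0.1350

    def test_search_children_split(self, final_h, ref_means):
        w = full_ahp(final_h, ref_means).weights
        assert np.round(
            [w.combination["2.1.1"], w.combination["2.1.2"]], 4
        ) == pytest.approx([0.1591, 0.0530])

    def test_missing_parent_vector_rejected(self, final_h):
        with pytest.raises(AhpError, match="missing local weight"):
            combine_weights(final_h, {None: {"1": 0.5, "2": 0.4, "3": 0.1}})


class TestFullAhp:
    def test_thirteen_matrices_all_pass(self, final_h, ref_means):
        report = full_ahp(final_h, ref_means)
        assert len(report.matrices) == 13
        assert all(c.passed for c in report.consistency.values())

    def test_cr_set_matches_reference(self, final_h, ref_means):
        crs = sorted(round(c.cr, 4) for c in full_ahp(final_h, ref_means).consistency.values())
        assert crs == sorted([0.0089, 0.0176, 0.0517, 0.0633] + [0.0] * 9)

    def test_all_31_weights_within_tolerance(self, final_h, ref_means, ref_weights):
        w = full_ahp(final_h, ref_means).weights.combination
        for iid, expected in ref_weights.items():
            assert w[iid] == pytest.approx(expected, abs=1e-3), iid

    def test_leaf_weights_sum_to_one(self, final_h, ref_means):
        report = full_ahp(final_h, ref_means)
        leaf_sum = sum(
            report.weights.combination[leaf.id] for leaf in final_h.leaves()
        )
        assert leaf_sum == pytest.approx(1.0, abs=1e-9)

    def test_children_sum_to_parent(self, final_h, ref_means):
        w = full_ahp(final_h, ref_means).weights.combination
        for parent in final_h.active():
            children = final_h.children_of(parent.id)
            if children:
                assert sum(w[c.id] for c in children) == pytest.approx(
                    w[parent.id], abs=1e-9
                )

    def test_reference_child_sum_spot_checks(self, final_h, ref_means):
        w = full_ahp(final_h, ref_means).weights.combination
        assert round(w["1.1.1"], 4) + round(w["1.1.2"], 4) == pytest.approx(0.2453)
        assert round(w["2.1.1"], 4) + round(w["2.1.2"], 4) == pytest.approx(0.2121)

    def test_equal_means_give_uniform_weights(self, final_h):
        report = full_ahp(final_h, {i.id: 4.0 for i in final_h.active()})
        for m in report.matrices.values():
            np.testing.assert_allclose(m.values, 1.0)
        for c in report.consistency.values():
            assert c.cr == pytest.approx(0.0)
        w = report.weights
        assert w.local["1"] == pytest.approx(1 / 3)

    def test_gate_failure_names_parent(self, final_h, ref_means):
        extreme = SaatyMapping(((0.0, 1), (math.inf, 9)))
        with pytest.raises(ConsistencyGateError) as exc:
            full_ahp(final_h, ref_means, mapping=extreme)
        assert "CR=" in str(exc.value)

    def test_force_overrides_gate(self, final_h, ref_means):
        extreme = SaatyMapping(((0.0, 1), (math.inf, 9)))
        report = full_ahp(final_h, ref_means, mapping=extreme, force=True)
        assert any(not c.passed for c in report.consistency.values())

    def test_missing_mean_rejected(self, final_h, ref_means):
        incomplete = dict(ref_means)
        incomplete.pop("2.2.2")
        with pytest.raises(AhpError, match="2.2.2"):
            full_ahp(final_h, incomplete)

    def test_leaf_rank_descending(self, final_h, ref_means):
        w = full_ahp(final_h, ref_means).weights
        ranked = sorted(w.leaf_rank.items(), key=lambda kv: kv[1])
        values = [w.combination[i] for i, _ in ranked]
        assert values == sorted(values, reverse=True)
        assert ranked[0][0] == "1.1.1"


class TestCalibrateMapping:
    def test_recovers_reference_scales(self):
        obs = [
            ((5.00, 5.00, 4.33), (0.4545, 0.4545, 0.0909)),
            ((5.00, 4.87, 4.80), (0.5396, 0.2970, 0.1634)),
            ((4.60, 4.47, 4.20), (0.5584, 0.3196, 0.1220)),
        ]
        mapping = calibrate_mapping(obs, max_scale=7)
        for diff, scale in [
            (0.13, 2),
            (0.07, 2),
            (0.20, 3),
            (0.27, 3),
            (0.40, 4),
            (0.67, 5),
        ]:
            assert mapping.scale(diff) == scale, diff

    def test_no_differences_degenerates_to_identity(self):
        mapping = calibrate_mapping([((4.0, 4.0), (0.5, 0.5))])
        assert mapping.scale(0.0) == 1
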