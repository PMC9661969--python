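import numpy as np
import pytest
from skbio import DistanceMatrix

from ecoassembly import EnvironmentalMatrix
from ecoassembly.envdecay import (
    distance_decay_regression,
    env_distance,
    impute_missing,
    mantel_p,
    screen_variables,
)


def env(values, variables=None, samples=None):
    values = np.asarray(values, dtype=float)
    variables = variables or [f"v{j}" for j in range(values.shape[1])]
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    return EnvironmentalMatrix(samples, variables, values)


class TestScreenVariables:
    def test_constant_column_removed(self):
        e = env([[1, 5], [1, 6], [1, 7], [1, 8]], variables=["const", "ok"])
        out, report = screen_variables(e)
        assert out.variables == ["ok"]
        assert report.removed_near_zero_variance == ["const"]

    def test_duplicated_column_drops_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        e = env(np.column_stack([x, x, y]), variables=["a", "a_copy", "b"])
        out, report = screen_variables(e, corr_threshold=0.9)
        assert len(report.removed_correlated) == 1
        assert report.removed_correlated[0] in ("a", "a_copy")
        assert "b" in out.variables

    def test_mean_abs_correlation_rule(self):
        # construct three variables where v0~v1 are nearly duplicates and
        # v0 also correlates moderately with v2, so v0 has the larger
        # mean |r| and must be the one removed
        rng = np.random.default_rng(1)
        base = rng.normal(size=40)
        other = 0.5 * base + rng.normal(scale=0.9, size=40)
        v0 = base
        v1 = base + rng.normal(scale=0.05, size=40)
        e = env(np.column_stack([v0, v1, other]), variables=["v0", "v1", "other"])
        corr = np.corrcoef(np.column_stack([v0, v1, other]).T)
        expected_drop = "v0" if np.abs(corr[0]).sum() >= np.abs(corr[1]).sum() else "v1"
        out, report = screen_variables(e, corr_threshold=0.9)
        assert report.removed_correlated == [expected_drop]

    def test_all_variables_removed_error(self):
        e = env([[1, 2], [1, 2], [1, 2]], variables=["c1", "c2"])
        with pytest.raises(ValueError, match="removed"):
            screen_variables(e)


class TestImputeMissing:
    def test_no_missing_is_identity(self):
        e = env([[1, 2], [3, 4], [5, 6]])
        out, logged = impute_missing(e, k=2)
        assert logged == []
        assert np.array_equal(out.values, e.values)

    def test_twin_row_fills_from_neighbour(self):
        vals = np.array(
            [[1.0, 10.0, 5.0], [1.0, 10.0, np.nan], [8.0, -3.0, 0.0], [4.0, 2.0, 7.0]]
        )
        out, logged = impute_missing(env(vals), k=1)
        assert out.values[1, 2] == pytest.approx(5.0)
        assert logged == [("s1", "v2")]

    def test_midpoint_row_takes_neighbour_mean(self):
        vals = np.array(
            [[0.0, 0.0, 2.0], [1.0, 1.0, np.nan], [2.0, 2.0, 8.0], [9.0, -9.0, 1.0]]
        )
        out, _ = impute_missing(env(vals), k=2)
        assert out.values[1, 2] == pytest.approx((2.0 + 8.0) / 2)

    def test_row_missing_everything_errors(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="missing all"):
            impute_missing(env(vals), k=1)


class TestEnvDistance:
    def test_identical_rows_distance_zero(self):
        e = env([[1, 2], [1, 2], [5, 9]])
        d = env_distance(e)
        assert d["s0", "s1"] == pytest.approx(0.0)

    def test_two_samples_one_variable_hand_value(self):
        e = env([[0.0], [2.0]])
        d = env_distance(e)
        # z-scores are -/+ 0.7071 (sd with n-1 is 1.4142), distance 1.4142
        assert d["s0", "s1"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 3))
        d1 = env_distance(env(vals))
        scaled = vals * np.array([100.0, 0.01, 3.0]) + np.array([5.0, -2.0, 0.0])
        d2 = env_distance(env(scaled))
        assert np.allclose(d1.data, d2.data)

    def test_zero_variance_variable_errors(self):
        e = env([[1, 1], [2, 1], [3, 1]])
        with pytest.raises(ValueError, match="zero-variance"):
            env_distance(e)


class TestDistanceDecayRegression:
    def test_exact_linear_relationship_recovered(self):
        ids = list("abcd")
        x = np.array(
            [[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], dtype=float
        )
        env_d = DistanceMatrix(x, ids=ids)
        # similarity values live off-diagonal; the diagonal is zeroed to
        # satisfy the distance-matrix container and is never used
        sim = DistanceMatrix((0.9 - 0.1 * x) * (1 - np.eye(4)), ids=ids)
        reg = distance_decay_regression(sim, env_d)
        assert reg.slope == pytest.approx(-0.1)
        assert reg.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        n = 7
        sym = rng.random((n, n))
        env_vals = rng.normal(size=(n, 2))
        from ecoassembly.envdecay import env_distance as ed

        env_d = ed(env(env_vals, samples=[f"s{i}" for i in range(n)]))
        simmat = (sym + sym.T) / 2
        np.fill_diagonal(simmat, 0)
        sim = DistanceMatrix(simmat, ids=[f"s{i}" for i in range(n)])
        reg = distance_decay_regression(sim, env_d)
        iu = np.triu_indices(n, k=1)
        x, y = env_d.data[iu], simmat[iu]
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.intercept == pytest.approx(beta[0])
        assert reg.slope == pytest.approx(beta[1])

    def test_constant_predictor_errors(self):
        ids = list("abc")
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]) * 1.0, ids=ids)
        sim = DistanceMatrix(
            np.array([[0, 0.5, 0.2], [0.5, 0, 0.4], [0.2, 0.4, 0]]), ids=ids
        )
        with pytest.raises(ValueError, match="constant"):
            distance_decay_regression(sim, d)

    def test_mantel_p_in_unit_interval(self):
        rng = np.random.default_rng(4)
        n = 6
        a = rng.random((n, n))
        simmat = (a + a.T) / 2
        np.fill_diagonal(simmat, 0)
        ids = [f"s{i}" for i in range(n)]
        sim = DistanceMatrix(simmat, ids=ids)
        env_d = env_distance(env(rng.normal(size=(n, 2)), samples=ids))
        p = mantel_p(sim, env_d, n_perm=99, seed=0)
        assert 0 < p <= 1
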