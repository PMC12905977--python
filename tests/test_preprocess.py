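import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylvar import (
    RelationshipMatrix,
    SimConfig,
    compute_relationship_matrix,
    filter_unrelated,
    residualize_and_standardize_markers,
    residualize_phenotype,
    simulate_cohort,
)
from tests.conftest import standardize_cols


def _cov(n, rng):
    return pd.DataFrame({"age": rng.uniform(20, 80, n), "sex": rng.integers(0, 2, n)})


class TestResidualizePhenotype:
    def test_orthogonal_phenotype_returned_mean_centred(self):
        rng = np.random.default_rng(0)
        cov = _cov(300, rng)
        y = rng.standard_normal(300)
        X = np.column_stack([np.ones(300), cov["age"], cov["age"] ** 2, cov["sex"]])
        y_orth = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        out = residualize_phenotype(y_orth + 5.0, cov)  # shift is absorbed by intercept
        np.testing.assert_allclose(out, y_orth, atol=1e-8)

    def test_perfect_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        cov = _cov(100, rng)
        out = residualize_phenotype(2.0 * cov["age"].to_numpy(), cov)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        cov = _cov(500, rng)
        out = residualize_phenotype(rng.standard_normal(500) + 0.2 * cov["age"], cov)
        X = np.column_stack([np.ones(500), cov["age"], cov["age"] ** 2, cov["sex"]])
        assert np.abs(X.T @ out).max() < 1e-6 * 500

    def test_recovers_planted_sex_effect(self):
        d = simulate_cohort(SimConfig(n_individuals=2000, n_probes=100, n_snps=100, seed=8))
        X = np.column_stack([
            np.ones(d.n), d.covariates["age"], d.covariates["age"] ** 2,
            d.covariates["sex"],
        ])
        coef, *_ = np.linalg.lstsq(X, d.phenotype, rcond=None)
        assert coef[3] == pytest.approx(14.0, abs=0.5)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(3)
        cov = _cov(50, rng)
        cov["dup"] = cov["sex"]
        with pytest.raises(ValueError, match="collinear.*(sex|dup)"):
            residualize_phenotype(rng.standard_normal(50), cov,
                                  extra_fixed_effects=["dup"])

    def test_missing_phenotype_rejected(self):
        rng = np.random.default_rng(4)
        cov = _cov(30, rng)
        y = rng.standard_normal(30)
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            residualize_phenotype(y, cov)


class TestResidualizeMarkers:
    def test_intercept_only_gives_plain_zscores(self):
        rng = np.random.default_rng(5)
        M = rng.uniform(0, 1, (200, 10))
        out = residualize_and_standardize_markers(M, [f"m{i}" for i in range(10)], None)
        np.testing.assert_allclose(out.values, standardize_cols(M), atol=1e-10)

    def test_columns_have_unit_variance_and_zero_mean(self, small_prepared):
        _, _, zm, _ = small_prepared
        assert np.abs(zm.values.mean(axis=0)).max() < 1e-8
        assert np.abs(zm.values.var(axis=0, ddof=1) - 1.0).max() < 1e-6

    def test_batch_indicator_column_is_dropped(self):
        rng = np.random.default_rng(6)
        n = 120
        cov = _cov(n, rng)
        cov["batch"] = rng.integers(0, 3, n)
        M = rng.uniform(0, 1, (n, 3))
        M[:, 1] = (cov["batch"] == 1).astype(float)  # pure batch signal
        out = residualize_and_standardize_markers(
            M, ["a", "b", "c"], cov, covariate_columns=("age", "sex", "batch"))
        assert out.dropped == ["b"]
        assert list(out.marker_ids) == ["a", "c"]

    def test_residuals_orthogonal_to_covariates(self, small_prepared):
        d, _, zm, _ = small_prepared
        from methylvar.preprocess import build_design

        X, _ = build_design(d.covariates)
        assert np.abs(X.T @ zm.values).max() < 1e-6 * d.n

    def test_double_residualization_is_noop(self, small_prepared):
        d, _, zm, _ = small_prepared
        again = residualize_and_standardize_markers(zm.values, zm.marker_ids, d.covariates)
        np.testing.assert_allclose(again.values, zm.values, atol=1e-8)

    def test_misaligned_covariates_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="aligned"):
            residualize_and_standardize_markers(
                rng.uniform(0, 1, (30, 4)), list("abcd"), _cov(29, rng))


class TestRelationshipMatrix:
    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        Z = standardize_cols(rng.standard_normal((50, 200)))
        from methylvar.preprocess import ResidualizedMatrix

        rm = compute_relationship_matrix(
            ResidualizedMatrix(Z, np.arange(200)), "ORM", chunk_size=37)
        brute = np.zeros((50, 50))
        for i in range(50):
            for k in range(50):
                brute[i, k] = sum(Z[i, j] * Z[k, j] for j in range(200)) / 200
        np.testing.assert_allclose(rm.values, brute, atol=1e-10)
        assert rm.n_markers == 200

    def test_identity_when_scaled_columns_orthonormal(self):
        n = 8
        Z = np.linalg.qr(np.random.default_rng(9).standard_normal((n, n)))[0] * np.sqrt(n)
        from methylvar.preprocess import ResidualizedMatrix

        rm = compute_relationship_matrix(ResidualizedMatrix(Z, np.arange(n)), "ORM")
        np.testing.assert_allclose(rm.values, np.eye(n), atol=1e-10)

    def test_duplicated_individuals_share_diagonal_value(self):
        rng = np.random.default_rng(10)
        Z = standardize_cols(rng.standard_normal((20, 100)))
        Z[1] = Z[0]
        from methylvar.preprocess import ResidualizedMatrix

        rm = compute_relationship_matrix(ResidualizedMatrix(Z, np.arange(100)), "GRM")
        assert rm.values[0, 1] == pytest.approx(rm.values[0, 0], abs=1e-10)

    def test_commutes_with_marker_permutation(self):
        rng = np.random.default_rng(11)
        Z = standardize_cols(rng.standard_normal((30, 60)))
        from methylvar.preprocess import ResidualizedMatrix

        a = compute_relationship_matrix(ResidualizedMatrix(Z, np.arange(60)), "ORM")
        perm = rng.permutation(60)
        b = compute_relationship_matrix(ResidualizedMatrix(Z[:, perm], perm), "ORM")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


def _greedy_reference(A, threshold):
    """Independently coded greedy: remove max-degree, keep lower index on ties."""
    n = A.shape[0]
    alive = set(range(n))
    while True:
        deg = {
            i: sum(1 for j in alive if j != i and abs(A[i, j]) >= threshold)
            for i in alive
        }
        worst = max(alive, key=lambda i: (deg[i], i))
        if deg[worst] == 0:
            break
        alive.remove(worst)
    return sorted(alive)


class TestFilterUnrelated:
    def test_identity_keeps_everyone(self):
        rel = RelationshipMatrix(np.eye(12), "GRM", 100)
        assert list(filter_unrelated(rel)) == list(range(12))

    def test_single_pair_removes_higher_index(self):
        A = np.eye(6)
        A[1, 4] = A[4, 1] = 0.5
        kept = filter_unrelated(RelationshipMatrix(A, "GRM", 10), 0.05)
        assert list(kept) == [0, 1, 2, 3, 5]

    def test_matches_reference_greedy_and_is_feasible(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            B = rng.normal(0, 0.05, (8, 8))
            A = (B + B.T) / 2
            np.fill_diagonal(A, 1.0)
            kept = list(filter_unrelated(RelationshipMatrix(A, "GRM", 10), 0.05))
            assert kept == _greedy_reference(A, 0.05)
            sub = A[np.ix_(kept, kept)]
            off = sub - np.diag(np.diag(sub))
            assert np.abs(off).max() < 0.05
            # greedy keeps no fewer than... sanity: it is a feasible subset of
            # the exhaustive maximum independent set problem
            best = 0
            for mask in range(1 << 8):
                idx = [i for i in range(8) if mask >> i & 1]
                ok = all(abs(A[i, j]) < 0.05 for i in idx for j in idx if i != j)
                if ok:
                    best = max(best, len(idx))
            assert len(kept) <= best

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_unrelated(RelationshipMatrix(np.eye(3), "GRM", 5), 0.0)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_projection_idempotence_property(seed):
    """Residualization is a projection: applying it twice equals once."""
    rng = np.random.default_rng(seed)
    n = 40
    cov = pd.DataFrame({"age": rng.uniform(20, 80, n), "sex": rng.integers(0, 2, n)})
    M = rng.uniform(0, 1, (n, 5))
    once = residualize_and_standardize_markers(M, list("abcde"), cov,
                                               covariate_columns=("age", "sex"))
    twice = residualize_and_standardize_markers(once.values, once.marker_ids, cov,
                                                covariate_columns=("age", "sex"))
    np.testing.assert_allclose(once.values, twice.values, atol=1e-8)
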