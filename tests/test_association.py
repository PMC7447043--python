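"""Association-model and meta-analysis tests: closed forms, degenerate
designs, an independent IRLS oracle, and simulation-based properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from nafldpheno import (
    AssociationResult,
    classify_significance,
    cochran_q,
    fit_snp_model,
    meta_fixed_effects,
)


def result(beta, se, rsid="rs0", stratum="EU"):
    return AssociationResult(rsid, stratum, beta, se, p=0.5, n=100, binary=True)


def irls_logistic(X, y, iters=50):
    """Independent Newton–Raphson logistic fit (oracle for the Wald route)."""
    X = np.column_stack([X, np.ones(len(y))])
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = expit(X @ beta)
        W = p * (1 - p)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))


class TestFitSnpModel:
    def test_matches_independent_irls(self):
        rng = np.random.default_rng(5)
        n = 3000
        dosage = rng.binomial(2, 0.3, n)
        age = rng.normal(60, 10, n)
        p = expit(-1.0 + 0.3 * dosage + 0.01 * (age - 60))
        y = rng.random(n) < p
        cov = pd.DataFrame({"age": age})
        res = fit_snp_model(dosage, y.astype(float), cov, binary=True)
        oracle_beta, oracle_se = irls_logistic(
            np.column_stack([dosage, age]), y.astype(float))
        assert res.beta == pytest.approx(oracle_beta[0], rel=1e-6)
        assert res.se == pytest.approx(oracle_se[0], rel=1e-4)

    def test_linear_outcome(self):
        rng = np.random.default_rng(6)
        n = 2000
        dosage = rng.binomial(2, 0.4, n)
        y = 1.5 * dosage + rng.normal(0, 2, n)
        res = fit_snp_model(dosage, y, binary=False)
        assert res.beta == pytest.approx(1.5, abs=0.2)
        assert res.or_ is None

    def test_constant_dosage_flagged(self):
        res = fit_snp_model(np.ones(100), np.r_[np.ones(50), np.zeros(50)])
        assert not res.estimable and "constant" in res.note

    def test_single_class_flagged(self):
        rng = np.random.default_rng(0)
        res = fit_snp_model(rng.binomial(2, 0.3, 100), np.ones(100))
        assert not res.estimable

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(8)
        dosage = rng.binomial(2, 0.3, 500)
        y = (rng.random(500) < expit(-0.5 + 0.4 * dosage)).astype(float)
        res = fit_snp_model(dosage, y, binary=True)
        assert res.ci95[0] < res.or_ < res.ci95[1]
        assert res.n_cases + res.n_controls == res.n


class TestMetaFixedEffects:
    def test_single_stratum_identity(self):
        meta = meta_fixed_effects([result(0.27, 0.01)])
        assert meta.beta == pytest.approx(0.27, abs=1e-15)
        assert meta.se == pytest.approx(0.01, abs=1e-15)
        assert meta.q_stat is None

    def test_identical_strata_shrink_root_k(self):
        meta = meta_fixed_effects([result(0.2, 0.1), result(0.2, 0.1)])
        assert meta.beta == pytest.approx(0.2, abs=1e-12)
        assert meta.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)

    def test_hand_computed_two_studies(self):
        meta = meta_fixed_effects([result(0.1, 0.1), result(0.3, 0.2)])
        # w = (100, 25): beta = (10 + 7.5)/125 = 0.14, se = 125^(-1/2)
        assert meta.beta == pytest.approx(0.14, abs=1e-12)
        assert meta.se == pytest.approx(125 ** -0.5, abs=1e-12)
        assert meta.q_stat == pytest.approx(0.80, abs=1e-12)
        assert meta.q_df == 1

    def test_rejects_empty_and_mixed(self):
        with pytest.raises(ValueError):
            meta_fixed_effects([])
        with pytest.raises(ValueError):
            meta_fixed_effects([result(0.1, 0.1, rsid="a"),
                                result(0.1, 0.1, rsid="b")])

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 1)),
                    min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_combined_beta_is_convex(self, studies):
        results = [result(b, s) for b, s in studies]
        meta = meta_fixed_effects(results)
        betas = [b for b, _ in studies]
        assert min(betas) - 1e-9 <= meta.beta <= max(betas) + 1e-9


class TestCochranQ:
    def test_identical_strata_no_heterogeneity(self):
        q, df, p = cochran_q([result(0.2, 0.1), result(0.2, 0.1)], 0.2)
        assert q == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_single_stratum_missing(self):
        assert cochran_q([result(0.2, 0.1)], 0.2) == (None, None, None)


class TestSignificanceTiers:
    @pytest.mark.parametrize("p,tier", [
        (1e-9, "genome_wide"), (5e-8, "experiment_wide"), (1e-6, "experiment_wide"),
        (1e-4, "replication"), (0.005, "replication"), (0.00625, "none"),
        (0.01, "none"), (1.0, "none"),
    ])
    def test_tiers(self, p, tier):
        assert classify_significance(p) == tier

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            classify_significance(bad)


class TestSimulationProperties:
    def _simulate_strata(self, beta, seed, n_per_stratum=4000, k=3):
        rng = np.random.default_rng(seed)
        results, pooled = [], []
        for s in range(k):
            dosage = rng.binomial(2, 0.3, n_per_stratum)
            y = (rng.random(n_per_stratum)
                 < expit(-0.8 + beta * dosage)).astype(float)
            results.append(fit_snp_model(dosage, y, binary=True,
                                         rsid="rs0", stratum=str(s)))
            pooled.append((dosage, y, np.full(n_per_stratum, s)))
        return results, pooled

    def test_meta_agrees_with_pooled_fit(self):
        results, pooled = self._simulate_strata(0.25, seed=13)
        meta = meta_fixed_effects(results)
        dosage = np.concatenate([d for d, _, _ in pooled])
        y = np.concatenate([y for _, y, _ in pooled])
        strat = np.concatenate([s for _, _, s in pooled])
        cov = pd.get_dummies(pd.Series(strat), prefix="s", drop_first=True,
                             dtype=float)
        pooled_fit = fit_snp_model(dosage, y, cov, binary=True)
        assert abs(meta.beta - pooled_fit.beta) < 2 * meta.se

    def test_covariates_with_no_effect_leave_estimate_stable(self):
        rng = np.random.default_rng(21)
        n = 6000
        dosage = rng.binomial(2, 0.3, n)
        y = (rng.random(n) < expit(-0.8 + 0.27 * dosage)).astype(float)
        noise = pd.DataFrame({"z1": rng.normal(size=n), "z2": rng.normal(size=n)})
        bare = fit_snp_model(dosage, y, binary=True)
        adjusted = fit_snp_model(dosage, y, noise, binary=True)
        assert abs(bare.beta - adjusted.beta) < 2 * bare.se
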