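"""Joint gene-factor model: conditionals, adaptation, invariants."""

import numpy as np
import pytest

from pleiofm.exceptions import DataError, ParameterError
from pleiofm.model import (
    ChainConfig,
    GeneFactorFineMapper,
    _ModelData,
    _init_state,
    _update_genes,
    adapt_truncation,
    gibbs_sweep,
)
from pleiofm.select import compute_pips


def _std(M):
    return (M - M.mean(0)) / M.std(0)


class TestChainConfig:
    def test_validation(self):
        with pytest.raises(ParameterError):
            ChainConfig(iterations=10, burn=10)
        with pytest.raises(ParameterError):
            ChainConfig(a1=1.0)


class TestFitBasics:
    def test_same_seed_identical_draws(self, tiny_signal_study):
        st = tiny_signal_study
        cfg = ChainConfig(iterations=60, burn=20, thin=1, m_init=3, m_max=3)
        fm = GeneFactorFineMapper(st.phenotypes, grex=st.grex_true, gene_ids=st.gene_ids, config=cfg)
        a = fm.fit(seed=9).draws
        b = fm.fit(seed=9).draws
        np.testing.assert_array_equal(a.B, b.B)
        np.testing.assert_array_equal(a.Lambda, b.Lambda)

    def test_exact_sparsity_of_stored_effects(self, tiny_signal_study):
        st = tiny_signal_study
        cfg = ChainConfig(iterations=120, burn=20, thin=1, m_init=3, m_max=3)
        res = GeneFactorFineMapper(
            st.phenotypes, grex=st.grex_true, gene_ids=st.gene_ids, config=cfg
        ).fit(seed=2)
        active = res.draws.I[:, :, None].astype(bool) & res.draws.U.astype(bool)
        assert np.all((res.draws.B != 0) == (active & (res.draws.B != 0)))
        assert np.all(res.draws.B[~active] == 0)

    def test_signal_recovery_and_summary(self, tiny_signal_study):
        st = tiny_signal_study
        cfg = ChainConfig(iterations=220, burn=120, thin=1, m_init=4, m_max=4)
        res = GeneFactorFineMapper(
            st.phenotypes, grex=st.grex_true, gene_ids=st.gene_ids, config=cfg
        ).fit(seed=3)
        causal = sorted(st.truth.causal_genes)[0]
        pips = res.pips().pip_omnibus
        assert np.argmax(pips) == causal
        assert pips[causal] > 0.9
        tab = res.summary()
        assert tab.iloc[0]["gene"] == st.gene_ids[causal]

    def test_missing_phenotypes_rejected(self, rng):
        Y = rng.standard_normal((50, 3))
        Y[0, 0] = np.nan
        with pytest.raises(DataError, match="missing"):
            GeneFactorFineMapper(Y, ["continuous"] * 3, grex=rng.standard_normal((50, 2)))

    def test_type_tags_validated(self, rng):
        Y = np.column_stack([rng.standard_normal(40), rng.standard_normal(40)])
        with pytest.raises(DataError, match="binary"):
            GeneFactorFineMapper(Y, ["binary", "continuous"], grex=rng.standard_normal((40, 2)))

    def test_covariates_residualized(self, rng):
        n = 200
        C = rng.standard_normal((n, 1))
        grex = _std(rng.standard_normal((n, 2)) + 2.0 * C)
        Y = rng.standard_normal((n, 3)) + 3.0 * C
        fm = GeneFactorFineMapper(Y, ["continuous"] * 3, grex=grex, covariates=C)
        assert np.all(np.abs(fm.grex.T @ C) / n < 1e-8)
        assert np.all(np.abs(fm.Y.T @ (C - C.mean())) / n < 1e-8)


class TestGenePermutationInvariance:
    def test_permuting_genes_permutes_pips(self, tiny_signal_study):
        st = tiny_signal_study
        cfg = ChainConfig(iterations=220, burn=120, thin=1, m_init=3, m_max=3)
        perm = np.array([3, 1, 4, 0, 2, 9, 6, 8, 7, 5])
        res1 = GeneFactorFineMapper(
            st.phenotypes, grex=st.grex_true, gene_ids=st.gene_ids, config=cfg
        ).fit(seed=4)
        res2 = GeneFactorFineMapper(
            st.phenotypes,
            grex=st.grex_true[:, perm],
            gene_ids=[st.gene_ids[j] for j in perm],
            config=cfg,
        ).fit(seed=4)
        p1 = res1.pips().pip_omnibus
        p2 = res2.pips().pip_omnibus
        # distributional invariance: same top gene, PIPs agree to MC error
        assert np.argmax(p2) == list(perm).index(np.argmax(p1))
        np.testing.assert_allclose(p1[perm], p2, atol=0.15)


class TestGeneBlockOracle:
    def test_inclusion_matches_exhaustive_enumeration(self, rng):
        """With Lambda, F, s2, omega2, pi fixed (m=1, continuous), the gene
        indicator chain must reproduce the exact enumeration posterior over
        the 2^p active sets computed with closed-form marginal likelihoods."""
        n, p = 80, 3
        X = _std(rng.standard_normal((n, p)))
        X[:, 1] = _std(0.7 * X[:, 0] + 0.3 * rng.standard_normal(n))  # correlated genes
        beta = np.array([0.4, 0.0, 0.0])
        omega2, s2, pi1, pi2 = 1.0, 0.8, 0.5, 0.5
        f = X @ beta + rng.standard_normal(n) * np.sqrt(omega2)

        # enumeration oracle over active sets A (gene active iff I_j U_j1 = 1)
        from itertools import product

        post = {}
        for pat in product([0, 1], repeat=p):
            A = [j for j in range(p) if pat[j]]
            C = omega2 * np.eye(n)
            if A:
                C += s2 * omega2 * X[:, A] @ X[:, A].T
            _, ld = np.linalg.slogdet(C)
            ll = -0.5 * (n * np.log(2 * np.pi) + ld + f @ np.linalg.solve(C, f))
            # P(I_j U_j = 1) = pi1 pi2; inactive = 1 - pi1 pi2 (I and U exchangeable here)
            pr = sum(
                np.log(pi1 * pi2) if b else np.log(1 - pi1 * pi2) for b in pat
            )
            post[pat] = ll + pr
        mx = max(post.values())
        Z = sum(np.exp(v - mx) for v in post.values())
        marg = np.array(
            [sum(np.exp(post[pat] - mx) / Z for pat in post if pat[j]) for j in range(p)]
        )

        data = _ModelData(f[:, None], ["continuous"], X)
        cfg = ChainConfig(iterations=2, burn=1)
        state = _init_state(data, cfg, rng)
        state.F = f[:, None]
        state.omega2 = np.array([omega2])
        state.s2 = s2
        state.pi1, state.pi2 = pi1, pi2
        state.U = state.U[:, :1].copy()
        state.b = state.b[:, :1].copy()
        state.B = state.B[:, :1].copy()
        count = np.zeros(p)
        n_iter = 20_000
        for _ in range(n_iter):
            _update_genes(state, data, rng)
            count += state.I * state.U[:, 0]
        np.testing.assert_allclose(count / n_iter, marg, atol=0.03)


class TestConjugateEffectUpdate:
    def test_forced_active_effects_match_closed_form(self, rng):
        # indicators forced on: b-update must sample the conjugate
        # Bayesian-linear-regression posterior for the factor regression
        n, p = 150, 2
        X = _std(rng.standard_normal((n, p)))
        omega2, s2 = 0.7, 2.0
        f = X @ np.array([0.5, -0.3]) + rng.standard_normal(n) * np.sqrt(omega2)
        data = _ModelData(f[:, None], ["continuous"], X)
        cfg = ChainConfig(iterations=2, burn=1)
        state = _init_state(data, cfg, rng)
        state.F = f[:, None]
        state.omega2 = np.array([omega2])
        state.s2 = s2
        state.pi1 = state.pi2 = 1 - 1e-12  # force indicators on
        state.U = np.ones((p, 1), dtype=bool)
        state.b = np.zeros((p, 1))
        state.B = np.zeros((p, 1))
        draws = []
        for _ in range(6000):
            _update_genes(state, data, rng)
            draws.append(state.b[:, 0].copy())
        draws = np.asarray(draws)[1000:]
        P = X.T @ X + np.eye(p) / s2
        mean = np.linalg.solve(P, X.T @ f)
        cov = omega2 * np.linalg.inv(P)
        tol = 4 * np.sqrt(np.diag(cov) / len(draws)) + 0.02
        assert np.all(np.abs(draws.mean(0) - mean) < tol)
        np.testing.assert_allclose(draws.var(0), np.diag(cov), rtol=0.15)


class TestAdaptiveTruncation:
    def _state_with_columns(self, rng, strong=2, total=5, q=12, n2=50, p=3):
        X = _std(rng.standard_normal((n2, p)))
        Lam = rng.standard_normal((q, total)) * 0.002
        Lam[:, :strong] = rng.standard_normal((q, strong)) * 2.0
        Y = rng.standard_normal((n2, q))
        data = _ModelData(Y, ["continuous"] * q, X)
        cfg = ChainConfig(iterations=2, burn=1, m_init=total, m_max=total,
                          adapt_alpha0=0.0, adapt_alpha1=0.0)  # adapt with probability 1
        state = _init_state(data, cfg, rng)
        state.Lambda = Lam
        state.tau2 = np.full(q, 1e-4)  # tight noise floor so 0.002 is negligible
        return state, data, cfg

    def test_prunes_to_strong_columns(self, rng):
        state, data, cfg = self._state_with_columns(rng)
        adapt_truncation(state, 1, cfg, data, rng)
        assert state.m == 2
        assert state.U.shape[1] == state.b.shape[1] == state.F.shape[1] == 2
        np.testing.assert_allclose(state.eta, np.cumprod(state.vartheta))

    def test_never_drops_below_one_column(self, rng):
        state, data, cfg = self._state_with_columns(rng, strong=0)
        adapt_truncation(state, 1, cfg, data, rng)
        assert state.m == 1

    def test_appends_when_no_column_negligible(self, rng):
        state, data, cfg = self._state_with_columns(rng, strong=5)
        cfg.m_max = 6
        adapt_truncation(state, 1, cfg, data, rng)
        assert state.m == 6

    def test_adaptation_probability_decreasing(self):
        cfg = ChainConfig(iterations=2, burn=1)
        probs = [np.exp(-cfg.adapt_alpha0 - cfg.adapt_alpha1 * t) for t in (1, 100, 10_000)]
        assert probs[0] > probs[1] > probs[2]

    def test_invalid_sweep_index(self, rng):
        state, data, cfg = self._state_with_columns(rng)
        with pytest.raises(ParameterError):
            adapt_truncation(state, 0, cfg, data, rng)


class TestShrinkagePrior:
    def test_prior_precision_stochastically_increasing_in_depth(self, rng):
        # eta_l = prod_{r<=l} theta_r with a1, a2 > 1: later factors carry
        # larger prior precision (stronger shrinkage) in expectation
        a1 = a2 = 3.0
        m, reps = 6, 20_000
        theta = np.column_stack(
            [rng.gamma(a1, size=reps)] + [rng.gamma(a2, size=reps) for _ in range(m - 1)]
        )
        eta = np.cumprod(theta, axis=1)
        means = eta.mean(axis=0)
        assert np.all(np.diff(means) > 0)

    def test_eta_invariant_after_sweeps(self, tiny_null_study, rng):
        st = tiny_null_study
        X = _std(st.grex_true)
        data = _ModelData(st.phenotypes.values, st.phenotypes.types, X)
        cfg = ChainConfig(iterations=2, burn=1, m_init=3, m_max=3)
        state = _init_state(data, cfg, rng)
        for _ in range(20):
            gibbs_sweep(state, data, cfg, rng)
            np.testing.assert_allclose(state.eta, np.cumprod(state.vartheta), rtol=1e-12)
            assert np.all(state.omega2 > 0) and np.all(state.tau2 > 0)
            assert 0 < state.pi1 < 1 and 0 < state.pi2 < 1

    def test_null_gene_inclusion_stays_low(self, tiny_null_study):
        st = tiny_null_study
        cfg = ChainConfig(iterations=300, burn=150, thin=1, m_init=3, m_max=3)
        res = GeneFactorFineMapper(
            st.phenotypes, grex=st.grex_true, gene_ids=st.gene_ids, config=cfg
        ).fit(seed=6)
        pips = compute_pips(res.draws).pip_omnibus
        # null posterior inclusion should stay below the prior mean (0.25 for
        # I*U under uniform priors) plus Monte-Carlo margin, on average
        assert pips.mean() < 0.25 + 0.15
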