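"""Joint Bayesian gene–factor fine-mapping model.

One genomic region at a time, the model links the imputed GReX of the
region's ``p`` candidate genes to ``q`` observed (possibly mixed-type)
phenotypes through ``m`` latent factors:

    f_l = sum_j beta_jl xhat_j + eps_l,          eps_l ~ N(0, omega_l^2 I)
    ytilde_i' = Lambda F_i + e_i,                e_i ~ N(0, Sigma)

with a two-level indicator (spike-and-slab) prior on the gene effects,

    beta_jl = I_j U_jl b_jl,   b_jl ~ N(0, s^2 omega_l^2),
    I_j ~ Ber(pi1), U_jl ~ Ber(pi2),

a multiplicative gamma-process shrinkage prior on the loadings,

    lambda_kl ~ N(0, phi_kl^-1 eta_l^-1),  phi_kl ~ Ga(3/2, 3/2),
    eta_l = prod_{r<=l} vartheta_r,  vartheta_1 ~ Ga(a1, 1), vartheta_h ~ Ga(a2, 1),

and Pólya-Gamma augmentation turning binary and count phenotypes into
heteroscedastic Gaussian pseudo-observations (see :mod:`pleiofm.augment`).
All full conditionals are conjugate, so posterior exploration is by Gibbs
sampling with an adaptive step that lets the data prune (or grow) the
factor truncation during burn-in.

The public surface follows the statsmodels convention:
``GeneFactorFineMapper(Y, types, grex).fit()`` returns a
:class:`FineMapResults` carrying the thinned posterior draws, posterior
inclusion probabilities, BFDR-controlled gene selection and a summary
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .augment import sample_polya_gamma, update_r
from .exceptions import DataError, NumericError, ParameterError

__all__ = [
    "ChainConfig",
    "JointState",
    "PosteriorDraws",
    "GeneFactorFineMapper",
    "FineMapResults",
    "gibbs_sweep",
    "adapt_truncation",
    "run_chain",
    "simulate_outcomes",
]


@dataclass
class ChainConfig:
    """Gibbs chain settings and hyperparameters.

    Variance hyperpriors are inverse-gamma ``IG(a0, b0)`` with the default
    ``(0, 0)`` recovering the scale-invariant Jeffreys prior; proper values
    are used by the prior-consistency diagnostics, which must forward-sample
    the prior.
    """

    iterations: int = 10_000
    burn: int = 5_000
    thin: int = 5
    m_init: Optional[int] = None      # default min(q, 15)
    m_max: Optional[int] = None       # default q
    a1: float = 3.0
    a2: float = 3.0
    adapt: bool = True                # adaptation runs during burn-in only
    adapt_alpha0: float = 1.0
    adapt_alpha1: float = 5e-4
    adapt_eps: float = 1e-2
    pg_trunc: int = 8
    fix_r: bool = False
    r_prior: tuple = (1.0, 0.01)
    pi_prior: tuple = (1.0, 1.0)
    # The slab scale s2 gets a weakly-informative proper IG(2, 1) prior rather
    # than a Jeffreys prior: with no active genes (a global null) a Jeffreys
    # prior leaves s2 unidentified and the (b, s2) subchain drifts as an
    # improper random walk whose small-s2 excursions erase the spike/slab
    # separation (the Bartlett-Lindley effect) and inflate null PIPs.  The
    # IG(2, 1) scale is natural here because GReX columns are standardized
    # and factors have roughly unit variance.  Set (0, 0) for Jeffreys.
    s2_prior: tuple = (2.0, 1.0)
    omega2_prior: tuple = (0.0, 0.0)
    tau2_prior: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.burn >= self.iterations:
            raise ParameterError("burn must be smaller than iterations")
        if self.a1 <= 1.0 or self.a2 <= 1.0:
            raise ParameterError("shrinkage hyperparameters a1, a2 must exceed 1")
        if self.thin < 1 or self.pg_trunc < 1:
            raise ParameterError("thin and pg_trunc must be >= 1")


@dataclass
class JointState:
    """One Gibbs state of the joint model (gene, factor and augmentation blocks)."""

    I: np.ndarray                    # (p,) gene-level indicators
    U: np.ndarray                    # (p, m) gene-by-factor indicators
    b: np.ndarray                    # (p, m) underlying effects
    B: np.ndarray                    # (p, m) = I * U * b
    pi1: float
    pi2: float
    s2: float
    omega2: np.ndarray               # (m,)
    Lambda: np.ndarray               # (q, m)
    F: np.ndarray                    # (n2, m)
    phi: np.ndarray                  # (q, m)
    vartheta: np.ndarray             # (m,)
    eta: np.ndarray                  # (m,) cumulative products of vartheta
    tau2: np.ndarray                 # (q,) residual variances (continuous columns)
    r: np.ndarray                    # (n_count,) NB dispersions
    psi: np.ndarray                  # (n2, q) PG draws (discrete entries only)
    zeta: np.ndarray                 # (n2, q) cached linear predictor F @ Lambda'

    @property
    def m(self) -> int:
        return self.Lambda.shape[1]


class _ModelData:
    """Preprocessed inputs shared by all sweep updates."""

    def __init__(self, Y, types, X):
        self.Y = np.asarray(Y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.types = list(types)
        t = np.asarray(self.types)
        self.cont = np.flatnonzero(t == "continuous")
        self.bin = np.flatnonzero(t == "binary")
        self.count = np.flatnonzero(t == "count")
        self.disc = np.concatenate([self.bin, self.count])
        self.xx = np.einsum("ij,ij->j", self.X, self.X)  # per-gene squared norms

    @property
    def n2(self):
        return self.Y.shape[0]

    @property
    def q(self):
        return self.Y.shape[1]

    @property
    def p(self):
        return self.X.shape[1]


def _mvn_batch(P, rhs, rng):
    """Draw x ~ N(P^-1 rhs, P^-1) for a batch of SPD precision matrices (B, m, m)."""
    L = np.linalg.cholesky(P)
    mu = np.linalg.solve(P, rhs[..., None])[..., 0]
    z = rng.standard_normal(mu.shape)
    w = np.linalg.solve(np.swapaxes(L, -1, -2), z[..., None])[..., 0]
    return mu + w


def _invgamma(shape, rate, rng):
    return np.asarray(rate) / rng.gamma(shape)


def _draw_psi(state: JointState, data: _ModelData, cfg: ChainConfig, rng):
    """PG auxiliaries for all discrete entries, tilted by the linear predictor."""
    if data.bin.size:
        state.psi[:, data.bin] = sample_polya_gamma(
            1.0, state.zeta[:, data.bin], rng, trunc=cfg.pg_trunc
        )
    if data.count.size:
        xi = data.Y[:, data.count] + state.r[None, :]
        state.psi[:, data.count] = sample_polya_gamma(
            xi, state.zeta[:, data.count], rng, trunc=cfg.pg_trunc
        )


def _pseudo_data(state: JointState, data: _ModelData):
    """Per-entry precision ``d`` and precision-weighted response ``d * ytilde``.

    For discrete entries ``d = psi`` and ``d * ytilde = kappa`` with
    ``kappa = y - xi/2``; continuous entries use ``d = 1/tau_k^2``.
    """
    d = np.empty_like(data.Y)
    dy = np.empty_like(data.Y)
    if data.cont.size:
        d[:, data.cont] = 1.0 / state.tau2[data.cont]
        dy[:, data.cont] = data.Y[:, data.cont] * d[:, data.cont]
    if data.bin.size:
        d[:, data.bin] = state.psi[:, data.bin]
        dy[:, data.bin] = data.Y[:, data.bin] - 0.5
    if data.count.size:
        d[:, data.count] = state.psi[:, data.count]
        dy[:, data.count] = 0.5 * (data.Y[:, data.count] - state.r[None, :])
    return d, dy


def _draw_F(state: JointState, data: _ModelData, d, dy, rng):
    m = state.m
    P = np.einsum("ik,kl,km->ilm", d, state.Lambda, state.Lambda, optimize=True)
    P[:, np.arange(m), np.arange(m)] += 1.0 / state.omega2
    rhs = (data.X @ state.B) / state.omega2 + dy @ state.Lambda
    state.F = _mvn_batch(P, rhs, rng)


def _draw_Lambda(state: JointState, data: _ModelData, d, dy, rng):
    m = state.m
    A = np.einsum("ik,il,im->klm", d, state.F, state.F, optimize=True)
    A[:, np.arange(m), np.arange(m)] += state.phi * state.eta
    rhs = dy.T @ state.F
    state.Lambda = _mvn_batch(A, rhs, rng)


def _draw_phi(state: JointState, rng):
    rate = 1.5 + 0.5 * state.eta * state.Lambda**2
    state.phi = rng.gamma(2.0, size=state.Lambda.shape) / rate


def _draw_vartheta(state: JointState, cfg: ChainConfig, rng):
    q, m = state.Lambda.shape
    ssq = np.einsum("kl,kl->l", state.phi, state.Lambda**2)
    for h in range(m):
        a_h = cfg.a1 if h == 0 else cfg.a2
        # eta_l with vartheta_h divided out, for l >= h
        eta_minus = np.cumprod(np.concatenate([[1.0], state.vartheta[h + 1 :]]))
        prefix = np.prod(state.vartheta[:h])
        rate = 1.0 + 0.5 * prefix * np.sum(eta_minus * ssq[h:])
        shape = a_h + 0.5 * q * (m - h)
        state.vartheta[h] = np.clip(rng.gamma(shape) / rate, 1e-8, 1e8)
    state.eta = np.cumprod(state.vartheta)


def _draw_tau2(state: JointState, data: _ModelData, cfg: ChainConfig, rng):
    if not data.cont.size:
        return
    a0, b0 = cfg.tau2_prior
    resid = data.Y[:, data.cont] - state.zeta[:, data.cont]
    ss = np.einsum("ik,ik->k", resid, resid)
    state.tau2[data.cont] = np.clip(
        _invgamma(a0 + 0.5 * data.n2, b0 + 0.5 * ss, rng), 1e-10, None
    )


def _update_genes(state: JointState, data: _ModelData, rng):
    """Collapsed update of (I, U, b): indicators drawn with b marginalised, then b redrawn."""
    X, xx = data.X, data.xx
    p, m = state.B.shape
    resid = state.F - X @ state.B
    log_pi2, log_1m_pi2 = np.log(state.pi2), np.log1p(-state.pi2)
    for j in range(p):
        rj = resid + np.outer(X[:, j], state.B[j])
        t = X[:, j] @ rj
        P = xx[j] + 1.0 / state.s2
        log_bf = -0.5 * np.log(state.s2 * P) + t**2 / (2.0 * state.omega2 * P)
        log_term = np.logaddexp(log_pi2 + log_bf, log_1m_pi2)
        I_j = rng.random() < expit(logit(state.pi1) + log_term.sum())
        if I_j:
            U_j = rng.random(m) < expit(log_pi2 - log_1m_pi2 + log_bf)
        else:
            U_j = rng.random(m) < state.pi2
        active = I_j & U_j
        z = rng.standard_normal(m)
        state.b[j] = np.where(
            active,
            t / P + np.sqrt(state.omega2 / P) * z,
            np.sqrt(state.s2 * state.omega2) * z,
        )
        state.I[j] = I_j
        state.U[j] = U_j
        state.B[j] = np.where(active, state.b[j], 0.0)
        resid = rj - np.outer(X[:, j], state.B[j])
    return resid


def _draw_pis(state: JointState, cfg: ChainConfig, rng):
    a0, b0 = cfg.pi_prior
    p, m = state.U.shape
    n1 = state.I.sum()
    state.pi1 = float(np.clip(rng.beta(a0 + n1, b0 + p - n1), 1e-12, 1 - 1e-12))
    nu = state.U.sum()
    state.pi2 = float(np.clip(rng.beta(a0 + nu, b0 + p * m - nu), 1e-12, 1 - 1e-12))


def _draw_scales(state: JointState, data: _ModelData, cfg: ChainConfig, resid, rng):
    p, m = state.b.shape
    a_s, b_s = cfg.s2_prior
    bw = state.b**2 / state.omega2
    state.s2 = float(
        np.clip(_invgamma(a_s + 0.5 * p * m, b_s + 0.5 * bw.sum(), rng), 1e-10, 1e10)
    )
    a_w, b_w = cfg.omega2_prior
    ssr = np.einsum("il,il->l", resid, resid)
    bsq = np.sum(state.b**2, axis=0) / state.s2
    state.omega2 = np.clip(
        _invgamma(a_w + 0.5 * (data.n2 + p), b_w + 0.5 * (ssr + bsq), rng), 1e-10, 1e10
    )


def _draw_r(state: JointState, data: _ModelData, cfg: ChainConfig, rng):
    for i, k in enumerate(data.count):
        state.r[i] = update_r(
            data.Y[:, k],
            state.zeta[:, k],
            state.r[i],
            rng,
            prior=cfg.r_prior,
            fixed=cfg.fix_r,
        )


_BLOCKS = ("psi", "F", "Lambda", "phi", "vartheta", "tau2", "genes", "pis", "scales", "r")


def _check_finite(state: JointState):
    for name in ("F", "Lambda", "B", "b", "omega2", "tau2", "eta", "psi", "r"):
        arr = getattr(state, name)
        if not np.all(np.isfinite(arr)):
            raise NumericError(f"non-finite draw in block {name!r}")
    for name in ("pi1", "pi2", "s2"):
        if not np.isfinite(getattr(state, name)):
            raise NumericError(f"non-finite draw in block {name!r}")


def gibbs_sweep(state: JointState, data: _ModelData, cfg: ChainConfig, rng) -> JointState:
    """One systematic scan over all full conditionals (in place)."""
    _draw_psi(state, data, cfg, rng)
    d, dy = _pseudo_data(state, data)
    _draw_F(state, data, d, dy, rng)
    _draw_Lambda(state, data, d, dy, rng)
    state.zeta = state.F @ state.Lambda.T
    _draw_phi(state, rng)
    _draw_vartheta(state, cfg, rng)
    _draw_tau2(state, data, cfg, rng)
    resid = _update_genes(state, data, rng)
    _draw_pis(state, cfg, rng)
    _draw_scales(state, data, cfg, resid, rng)
    _draw_r(state, data, cfg, rng)
    return state


def adapt_truncation(state: JointState, sweep_index: int, cfg: ChainConfig, data, rng):
    """Prune all-negligible loading columns, or grow by one, with vanishing probability."""
    if sweep_index < 1:
        raise ParameterError("sweep_index must be >= 1")
    if rng.random() >= np.exp(-cfg.adapt_alpha0 - cfg.adapt_alpha1 * sweep_index):
        return state
    m = state.m
    m_max = cfg.m_max if cfg.m_max is not None else data.q
    # a loading is "negligible" when below both the configured threshold and
    # its own posterior noise floor ~ 3/sqrt(n2 * mean precision); a fixed
    # absolute eps below that floor would never prune and m would only grow
    d, _ = _pseudo_data(state, data)
    floor = 3.0 / np.sqrt(np.maximum(data.n2 * d.mean(axis=0), 1e-12))  # per phenotype
    eps = np.maximum(cfg.adapt_eps, floor)[:, None]
    small = np.all(np.abs(state.Lambda) < eps, axis=0)
    if small.all() and m > 1:
        keep_one = int(np.argmax(np.abs(state.Lambda).max(axis=0)))
        small[keep_one] = False
    if small.any() and m > 1:
        keep = ~small
        state.Lambda = state.Lambda[:, keep]
        state.U = state.U[:, keep]
        state.b = state.b[:, keep]
        state.B = state.B[:, keep]
        state.F = state.F[:, keep]
        state.phi = state.phi[:, keep]
        state.omega2 = state.omega2[keep]
        state.vartheta = state.vartheta[keep]
        state.eta = np.cumprod(state.vartheta)
    elif not small.any() and m < m_max:
        q, p = data.q, data.p
        vt = np.clip(rng.gamma(cfg.a2), 1e-8, 1e8)
        state.vartheta = np.append(state.vartheta, vt)
        state.eta = np.cumprod(state.vartheta)
        phi_new = rng.gamma(1.5, size=q) / 1.5
        lam_new = rng.standard_normal(q) / np.sqrt(phi_new * state.eta[-1])
        w2 = float(state.omega2.mean())
        b_new = rng.standard_normal(p) * np.sqrt(state.s2 * w2)
        U_new = rng.random(p) < state.pi2
        B_new = np.where(state.I.astype(bool) & U_new, b_new, 0.0)
        F_new = data.X @ B_new + rng.standard_normal(data.n2) * np.sqrt(w2)
        state.Lambda = np.column_stack([state.Lambda, lam_new])
        state.phi = np.column_stack([state.phi, phi_new])
        state.U = np.column_stack([state.U, U_new])
        state.b = np.column_stack([state.b, b_new])
        state.B = np.column_stack([state.B, B_new])
        state.F = np.column_stack([state.F, F_new])
        state.omega2 = np.append(state.omega2, w2)
    state.zeta = state.F @ state.Lambda.T
    return state


def simulate_outcomes(state: JointState, data: _ModelData, rng) -> np.ndarray:
    """Draw Y from the observation model at the current parameters.

    Used by the prior-consistency (successive-conditional) diagnostic and
    for posterior predictive checks.
    """
    Y = np.empty((data.n2, data.q))
    zeta = state.F @ state.Lambda.T
    if data.cont.size:
        Y[:, data.cont] = zeta[:, data.cont] + rng.standard_normal(
            (data.n2, data.cont.size)
        ) * np.sqrt(state.tau2[data.cont])
    if data.bin.size:
        Y[:, data.bin] = rng.random((data.n2, data.bin.size)) < expit(zeta[:, data.bin])
    for i, k in enumerate(data.count):
        Y[:, k] = rng.negative_binomial(state.r[i], expit(-zeta[:, k]))
    return Y


def _init_state(data: _ModelData, cfg: ChainConfig, rng) -> JointState:
    n2, q, p = data.n2, data.q, data.p
    m0 = cfg.m_init if cfg.m_init is not None else min(q, 15)
    m0 = min(m0, cfg.m_max if cfg.m_max is not None else q)

    # warm start: SVD on a Gaussianised proxy of Y (log1p for counts) so raw
    # count magnitudes do not distort the initial factor space
    ystd = data.Y.copy()
    if data.count.size:
        ystd[:, data.count] = np.log1p(ystd[:, data.count])
    sd = ystd.std(axis=0)
    ystd = (ystd - ystd.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    U_svd, S, Vt = np.linalg.svd(ystd, full_matrices=False)
    m0 = min(m0, S.size)
    Lam = Vt[:m0].T * (S[:m0] / np.sqrt(n2))
    F = U_svd[:, :m0] * np.sqrt(n2)

    I = np.ones(p, dtype=bool)
    U = np.ones((p, m0), dtype=bool)
    b = np.linalg.solve(data.X.T @ data.X + np.eye(p), data.X.T @ F)
    B = b.copy()
    omega2 = np.maximum((F - data.X @ B).var(axis=0), 1e-2)
    s2 = float(np.clip(np.mean(b**2 / omega2), 1e-3, 1e3))
    tau2 = np.ones(q)
    if data.cont.size:
        resid = data.Y[:, data.cont] - (F @ Lam.T)[:, data.cont]
        tau2[data.cont] = np.maximum(resid.var(axis=0), 1e-4)
    r = np.empty(data.count.size)
    for i, k in enumerate(data.count):
        y = data.Y[:, k]
        r[i] = np.clip(y.mean() ** 2 / max(y.var() - y.mean(), 0.1), 0.5, 50.0)
    psi = np.zeros((n2, q))
    if data.bin.size:
        psi[:, data.bin] = 0.25
    if data.count.size:
        psi[:, data.count] = (data.Y[:, data.count] + r[None, :]) / 4.0
    return JointState(
        I=I,
        U=U,
        b=b,
        B=B,
        pi1=0.5,
        pi2=0.5,
        s2=s2,
        omega2=omega2,
        Lambda=Lam,
        F=F,
        phi=np.ones((q, m0)),
        vartheta=np.ones(m0),
        eta=np.ones(m0),
        tau2=tau2,
        r=r,
        psi=psi,
        zeta=F @ Lam.T,
    )


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws; truncation is frozen after burn-in so all
    factor-indexed arrays share the same m."""

    I: np.ndarray                    # (D, p)
    U: np.ndarray                    # (D, p, m)
    B: np.ndarray                    # (D, p, m)
    Lambda: np.ndarray               # (D, q, m)
    omega2: np.ndarray               # (D, m)
    r: np.ndarray                    # (D, n_count)
    m_trajectory: np.ndarray         # (iterations,)
    Lambda_ref: np.ndarray           # (q, m) alignment reference (last burn-in draw)
    F_mean: np.ndarray               # (n2, m)
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.I.shape[0]


def run_chain(grex, Y, types, cfg: ChainConfig, seed=None, gene_ids=None, phenotype_ids=None):
    """Run one region's Gibbs chain and return :class:`PosteriorDraws`."""
    data = _ModelData(Y, types, grex)
    rng = np.random.default_rng(seed)
    state = _init_state(data, cfg, rng)
    n_store = (cfg.iterations - cfg.burn + cfg.thin - 1) // cfg.thin
    stored = {k: [] for k in ("I", "U", "B", "Lambda", "omega2", "r")}
    m_traj = np.empty(cfg.iterations, dtype=int)
    Lambda_ref = None
    F_sum = None
    for it in range(cfg.iterations):
        try:
            gibbs_sweep(state, data, cfg, rng)
            if cfg.adapt and it < cfg.burn:
                adapt_truncation(state, it + 1, cfg, data, rng)
            _check_finite(state)
        except NumericError as err:
            raise NumericError(f"sweep {it}: {err}") from err
        m_traj[it] = state.m
        if it == cfg.burn - 1 or (cfg.burn == 0 and it == 0 and Lambda_ref is None):
            Lambda_ref = state.Lambda.copy()
        if it >= cfg.burn and (it - cfg.burn) % cfg.thin == 0:
            stored["I"].append(state.I.copy())
            stored["U"].append(state.U.copy())
            stored["B"].append(state.B.copy())
            stored["Lambda"].append(state.Lambda.copy())
            stored["omega2"].append(state.omega2.copy())
            stored["r"].append(state.r.copy())
            F_sum = state.F.copy() if F_sum is None else F_sum + state.F
    if Lambda_ref is None:
        Lambda_ref = state.Lambda.copy()
    draws = PosteriorDraws(
        I=np.array(stored["I"]),
        U=np.array(stored["U"]),
        B=np.array(stored["B"]),
        Lambda=np.array(stored["Lambda"]),
        omega2=np.array(stored["omega2"]),
        r=np.array(stored["r"]),
        m_trajectory=m_traj,
        Lambda_ref=Lambda_ref,
        F_mean=F_sum / n_store if F_sum is not None else state.F,
        meta={
            "iterations": cfg.iterations,
            "burn": cfg.burn,
            "thin": cfg.thin,
            "seed": seed,
            "m": state.m,
            "gene_ids": list(gene_ids) if gene_ids is not None else None,
            "phenotype_ids": list(phenotype_ids) if phenotype_ids is not None else None,
            "types": list(types),
        },
    )
    return draws


class GeneFactorFineMapper:
    """Joint fine-mapping of one region's genes against mixed-type phenotypes.

    Parameters
    ----------
    Y : (n2, q) phenotype matrix, array or DataFrame (or PhenotypeTable).
        No missing values are allowed.
    phenotype_types : per-column tags in {"continuous", "binary", "count"}.
    grex : (n2, p) imputed GReX, array / DataFrame / GReXMatrix; columns are
        standardized internally.
    covariates : optional (n2, c) matrix; residualised out of GReX and
        continuous phenotype columns (discrete columns are left untouched).
    """

    def __init__(
        self,
        Y,
        phenotype_types=None,
        grex=None,
        gene_ids=None,
        phenotype_ids=None,
        covariates=None,
        config: Optional[ChainConfig] = None,
    ):
        from .simulate import PhenotypeTable  # local import to avoid cycle

        if isinstance(Y, PhenotypeTable):
            phenotype_ids = phenotype_ids or list(Y.ids)
            phenotype_types = phenotype_types or list(Y.types)
            Y = Y.values
        if isinstance(Y, pd.DataFrame):
            phenotype_ids = phenotype_ids or list(Y.columns)
            Y = Y.to_numpy(dtype=float)
        Y = np.asarray(Y, dtype=float)
        if phenotype_types is None:
            raise ParameterError("phenotype_types is required")
        if grex is None:
            raise ParameterError("grex is required")
        if hasattr(grex, "values") and hasattr(grex, "gene_ids"):  # GReXMatrix
            gene_ids = gene_ids or list(grex.gene_ids)
            grex = grex.values
        if isinstance(grex, pd.DataFrame):
            gene_ids = gene_ids or list(grex.columns)
            grex = grex.to_numpy(dtype=float)
        grex = np.asarray(grex, dtype=float)
        if Y.ndim != 2 or grex.ndim != 2 or Y.shape[0] != grex.shape[0]:
            raise ParameterError("Y and grex must be 2-D with matching rows")
        if len(phenotype_types) != Y.shape[1]:
            raise ParameterError("one phenotype type per Y column required")
        if np.isnan(Y).any():
            raise DataError("missing phenotype entries are not supported; drop incomplete rows")
        if not np.all(np.isfinite(grex)):
            raise DataError("grex must be finite")
        types = list(phenotype_types)
        for k, tk in enumerate(types):
            col = Y[:, k]
            if tk == "binary" and np.any((col != 0) & (col != 1)):
                raise DataError(f"phenotype column {k} tagged binary but is not 0/1")
            if tk == "count" and (np.any(col < 0) or np.any(col != np.round(col))):
                raise DataError(f"phenotype column {k} tagged count but is not a non-negative integer")

        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            C = np.column_stack([np.ones(C.shape[0]), C])
            proj = lambda v: v - C @ np.linalg.lstsq(C, v, rcond=None)[0]
            grex = proj(grex)
            Y = Y.copy()
            cont = [k for k, tk in enumerate(types) if tk == "continuous"]
            if cont:
                Y[:, cont] = proj(Y[:, cont])
            if any(tk != "continuous" for tk in types):
                warnings.warn(
                    "covariates are residualised out of GReX and continuous phenotypes only; "
                    "discrete phenotypes are left unadjusted",
                    stacklevel=2,
                )
        # standardize GReX columns, center continuous phenotypes
        mu, sd = grex.mean(axis=0), grex.std(axis=0)
        if np.any(sd == 0):
            raise DataError("constant GReX column; drop the gene before fitting")
        grex = (grex - mu) / sd
        Y = Y.copy()
        cont = [k for k, tk in enumerate(types) if tk == "continuous"]
        if cont:
            Y[:, cont] -= Y[:, cont].mean(axis=0)

        self.Y = Y
        self.grex = grex
        self.types = types
        self.gene_ids = list(gene_ids) if gene_ids is not None else [f"gene{j}" for j in range(grex.shape[1])]
        self.phenotype_ids = (
            list(phenotype_ids) if phenotype_ids is not None else [f"ph{k:03d}" for k in range(Y.shape[1])]
        )
        self.config = config or ChainConfig()

    @classmethod
    def from_frames(cls, Y_df, types, grex_df, **kwargs):
        return cls(Y_df, phenotype_types=types, grex=grex_df, **kwargs)

    def fit(self, seed=None, config: Optional[ChainConfig] = None) -> "FineMapResults":
        cfg = config or self.config
        draws = run_chain(
            self.grex,
            self.Y,
            self.types,
            cfg,
            seed=seed,
            gene_ids=self.gene_ids,
            phenotype_ids=self.phenotype_ids,
        )
        return FineMapResults(self, draws, cfg)


class FineMapResults:
    """Posterior summaries of one fitted region."""

    def __init__(self, model: GeneFactorFineMapper, draws: PosteriorDraws, config: ChainConfig):
        self.model = model
        self.draws = draws
        self.config = config
        self._pips = None

    @property
    def n_draws(self):
        return self.draws.n_draws

    @property
    def m(self):
        return self.draws.meta["m"]

    def pips(self):
        from .select import compute_pips

        if self._pips is None:
            self._pips = compute_pips(self.draws)
        return self._pips

    def select(self, alpha=0.1, mode="omnibus"):
        from .select import select_genes

        return select_genes(self.pips(), alpha=alpha, mode=mode, gene_ids=self.model.gene_ids)

    def loading_summary(self) -> pd.DataFrame:
        from .select import aligned_loading_mean

        lam = aligned_loading_mean(self.draws)
        return pd.DataFrame(
            lam, index=self.model.phenotype_ids, columns=[f"factor{l+1}" for l in range(lam.shape[1])]
        )

    def summary(self, alpha=0.1) -> pd.DataFrame:
        pips = self.pips()
        sel = self.select(alpha=alpha)
        tab = pd.DataFrame(
            {
                "gene": self.model.gene_ids,
                "pip_omnibus": pips.pip_omnibus,
                "selected": [g in set(sel.selected_genes) for g in self.model.gene_ids],
            }
        )
        for l in range(pips.pip_factor.shape[1]):
            tab[f"pip_factor{l+1}"] = pips.pip_factor[:, l]
        tab["b_mean"] = self.draws.B.mean(axis=0).max(axis=1)
        return tab.sort_values("pip_omnibus", ascending=False).reset_index(drop=True)

    def plot_loadings(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, max(3, 0.2 * len(self.model.phenotype_ids))))
        lam = self.loading_summary()
        im = ax.imshow(lam.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_yticks(range(len(lam.index)), lam.index, fontsize=6)
        ax.set_xticks(range(lam.shape[1]), lam.columns)
        ax.figure.colorbar(im, ax=ax, label="posterior mean loading")
        return ax

    def plot_pip_trace(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        active = self.draws.I.mean(axis=1)
        ax.plot(active)
        ax.set_xlabel("stored draw")
        ax.set_ylabel("fraction of active genes")
        return ax
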