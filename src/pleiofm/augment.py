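"""Pólya-Gamma data augmentation for mixed-type outcomes.

Binary and count phenotypes enter the joint factor model through the
Pólya-Gamma (PG) auxiliary-variable scheme: conditional on a PG draw
``psi`` the logistic / negative-binomial likelihood of an outcome ``y``
with linear predictor ``zeta`` is proportional to a Gaussian likelihood
for the pseudo-observation ``y_tilde = kappa / psi`` with precision
``psi``, where ``kappa = y - xi/2`` and

* binary: ``xi = 1``,
* count (negative binomial with ``r`` successes): ``xi = y + r``.

Continuous outcomes pass through unchanged.  This module provides the PG
sampler, the response transform, and the Gibbs update of the
negative-binomial dispersion ``r`` via the Chinese-restaurant-table (CRT)
latent count representation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma

__all__ = [
    "pg_mean",
    "pg_var",
    "sample_polya_gamma",
    "augment_response",
    "crt_total",
    "update_r",
]

_TWO_PI_SQ = 2.0 * np.pi**2

# Closed-form series constants: PG(b, c) = (1/2pi^2) sum_k g_k / d_k with
# g_k ~ Ga(b, 1) and d_k = (k - 1/2)^2 + c^2 / (4 pi^2).
_S1_FULL = np.pi**2 / 2.0  # sum_k (k-1/2)^-2
_S2_FULL = np.pi**4 / 6.0  # sum_k (k-1/2)^-4


def pg_mean(b, c):
    """Mean of PG(b, c): ``b/(2c) tanh(c/2)``, with the ``c -> 0`` limit ``b/4``."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    small = np.abs(c) < 1e-6
    cs = np.where(small, 1.0, c)
    out = b / (2.0 * cs) * np.tanh(cs / 2.0)
    # series: tanh(c/2)/(2c) = 1/4 - c^2/48 + O(c^4)
    return np.where(small, b * (0.25 - c**2 / 48.0), out)


def pg_var(b, c):
    """Variance of PG(b, c): ``b (sinh c - c) sech^2(c/2) / (4 c^3)``, limit ``b/24``."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    small = np.abs(c) < 1e-4
    cs = np.where(small, 1.0, c)
    out = b * (np.sinh(cs) - cs) / (4.0 * cs**3) / np.cosh(cs / 2.0) ** 2
    return np.where(small, b / 24.0, out)


def _series_sums(c, trunc):
    """Partial and tail sums of ``1/d_k`` and ``1/d_k^2`` for the PG series."""
    h2 = (c / (2.0 * np.pi)) ** 2
    k = np.arange(1, trunc + 1)
    d = (k - 0.5) ** 2 + h2[..., None]
    s1_head = np.sum(1.0 / d, axis=-1)
    s2_head = np.sum(1.0 / d**2, axis=-1)
    # Full sums follow from the closed-form PG moments:
    # E[PG(b,c)] = b/(2pi^2) sum 1/d_k, Var[PG(b,c)] = b/(4pi^4) sum 1/d_k^2.
    s1_full = _TWO_PI_SQ * pg_mean(1.0, c)
    s2_full = 4.0 * np.pi**4 * pg_var(1.0, c)
    return np.maximum(s1_full - s1_head, 0.0), np.maximum(s2_full - s2_head, 0.0), d


def sample_polya_gamma(b, c, rng, trunc=200, normal_threshold=170.0):
    """Draw PG(b, c) variates, elementwise over broadcast ``b`` and ``c``.

    Uses the infinite sum-of-gammas representation truncated at ``trunc``
    terms, with the remaining tail replaced by a single gamma variate whose
    mean and variance match the analytic tail exactly, so the first two
    moments of the draw are exact at any truncation.  Entries with
    ``b >= normal_threshold`` use a normal approximation (the PG is then a
    sum of many independent terms).

    Parameters
    ----------
    b : array_like, positive
        Shape parameter; real values are supported (count outcomes give
        ``b = y + r``).
    c : array_like
        Tilt parameter; the distribution is symmetric in ``c``.
    rng : numpy.random.Generator
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(b <= 0):
        raise ValueError("PG shape parameter b must be positive and finite")
    b, c = np.broadcast_arrays(b, c)
    b = np.ascontiguousarray(b)
    c = np.ascontiguousarray(c)
    out = np.empty(b.shape, dtype=float)

    big = b >= normal_threshold
    if np.any(big):
        mu = pg_mean(b[big], c[big])
        sd = np.sqrt(pg_var(b[big], c[big]))
        out[big] = np.maximum(mu + sd * rng.standard_normal(mu.shape), 1e-12)
    rest = ~big
    if np.any(rest):
        br, cr = b[rest], c[rest]
        s1_tail, s2_tail, d = _series_sums(cr, trunc)
        if np.all(br == 1.0):  # logistic case: Ga(1,1) draws are exponentials
            g = rng.standard_exponential(d.shape)
        else:
            g = rng.gamma(br[..., None], size=d.shape)
        head = np.sum(g / d, axis=-1)
        tail_mean = br * s1_tail
        tail_var = br * s2_tail
        with np.errstate(divide="ignore", invalid="ignore"):
            shape = np.where(tail_var > 0, tail_mean**2 / np.maximum(tail_var, 1e-300), 0.0)
            scale = np.where(tail_mean > 0, tail_var / np.maximum(tail_mean, 1e-300), 0.0)
        tail = np.where(shape > 0, rng.gamma(np.maximum(shape, 1e-12)) * scale, 0.0)
        out[rest] = (head + tail) / _TWO_PI_SQ
    return out if out.ndim else float(out)


def augment_response(y, outcome_type, psi=None, r=None):
    """Transformed response ``y_tilde`` of the unified Gaussian pseudo-likelihood.

    continuous -> ``y``; binary -> ``(y - 0.5)/psi``; count -> ``(y - (y+r)/2)/psi``
    (equivalently ``(y - r)/(2 psi)``).
    """
    y = np.asarray(y, dtype=float)
    if outcome_type == "continuous":
        return y
    psi = np.asarray(psi, dtype=float)
    if np.any(psi <= 0):
        raise ValueError("psi must be positive for discrete outcomes")
    if outcome_type == "binary":
        if np.any((y != 0) & (y != 1)):
            raise ValueError("binary outcomes must be 0/1")
        return (y - 0.5) / psi
    if outcome_type == "count":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("count outcomes must be non-negative integers")
        if r is None or np.any(np.asarray(r) <= 0):
            raise ValueError("count outcomes require a positive dispersion r")
        return (y - 0.5 * (y + r)) / psi
    raise ValueError(f"unknown outcome type: {outcome_type!r}")


def crt_total(y, r, rng, exact_limit=64):
    """Total CRT table count ``sum_i L_i`` with ``L_i = sum_{t=1}^{y_i} Ber(r/(r+t-1))``.

    Only the total is needed for the conjugate gamma update of ``r``, so the
    sum is drawn as a sequence of binomials over table positions ``t``.
    Positions beyond ``exact_limit`` (where every success probability is
    below ``r/(r+exact_limit)``) are pooled into a single Poisson draw with
    the exact aggregate mean, which keeps the update O(exact_limit) even for
    heavy-tailed count columns.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    y = y.astype(np.int64)
    ymax = int(y.max(initial=0))
    if ymax == 0:
        return 0
    ys = np.sort(y)
    t = np.arange(1, min(ymax, exact_limit) + 1)
    n_ge = y.size - np.searchsorted(ys, t, side="left")  # #{y >= t}
    p = np.minimum(r / (r + (t - 1.0)), 1.0)
    total = int(rng.binomial(n_ge, p).sum())
    if ymax > exact_limit:
        # aggregate mean over positions t > exact_limit via the digamma
        # identity sum_{t=a}^{y} 1/(r+t-1) = psi(y+r) - psi(a-1+r), which
        # stays O(n) even for extreme counts
        big = y[y > exact_limit].astype(float)
        mu = float(r * np.sum(digamma(big + r) - digamma(exact_limit + r)))
        total += rng.poisson(mu)
    return total


def update_r(y_col, linear_pred, r_current, rng, prior=(1.0, 0.01), fixed=False):
    """One Gibbs draw of the negative-binomial dispersion ``r``.

    Uses the CRT latent-count augmentation: with ``L`` total tables and
    linear predictor ``zeta``, ``r | L, zeta ~ Ga(a0 + L, b0 + sum_i
    log(1 + exp(zeta_i)))`` for a ``Ga(a0, b0)`` prior.
    """
    if fixed:
        return float(r_current)
    y = np.asarray(y_col)
    zeta = np.asarray(linear_pred, dtype=float)
    a0, b0 = prior
    L = crt_total(y, float(r_current), rng)
    rate = b0 + float(np.sum(np.logaddexp(0.0, zeta)))
    draw = rng.gamma(a0 + L) / rate
    # keep r in a numerically safe range; r ~ 1e4 is already effectively Poisson
    return float(np.clip(draw, 1e-3, 1e4))
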