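"""Per-gene Bayesian sparse expression models and GReX imputation.

The expression model for gene *j* regresses reference-panel expression on
the gene's standardized cis-SNP dosages,

    x_j = Z_j gamma_j + eps_j,   eps_j ~ N(0, sigma_j^2 I),

with a spike-and-slab prior on each SNP effect,

    gamma_d ~ I_d delta_0 + (1 - I_d) N(0, v_j^2 sigma_j^2),
    I_d ~ Bernoulli(pi),

so the indicator ``I_d = 1`` selects the spike (zero) component.  The
hyperpriors are pi ~ Uniform(0,1) and Jeffreys priors on v_j^2 and
sigma_j^2.  The posterior is explored by Gibbs sampling; the posterior
mean of gamma is then used to impute genetically regulated expression
(GReX) into a GWAS cohort, ``xhat_j = Z_j^G gamma_hat_j``.

Fitting is vectorised internally across genes that share the same number
of cis-SNPs, which is the common case when training a whole region at
once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import (
    DataError,
    FormatError,
    InsufficientDataError,
    MissingSNPError,
    ParameterError,
)

__all__ = [
    "GeneWeights",
    "GReXMatrix",
    "SparseExpressionModel",
    "SparseExpressionResults",
    "fit_gene_weights",
    "fit_region_weights",
    "impute_grex",
    "read_weights",
    "write_weights",
]


@dataclass
class GeneWeights:
    """Posterior summaries of one gene's cis-SNP effect vector."""

    gene_id: str
    snp_ids: list
    gamma_hat: np.ndarray          # posterior-mean effect per SNP
    spike_prob: Optional[np.ndarray] = None  # P(I_d = 1 | data): probability of the zero component
    sigma2_hat: Optional[float] = None
    v2_hat: Optional[float] = None
    extra: dict = field(default_factory=dict)  # unknown TSV columns, preserved on round-trip

    def __post_init__(self):
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        if len(self.snp_ids) != self.gamma_hat.shape[0]:
            raise ParameterError("snp_ids and gamma_hat length mismatch")
        if self.spike_prob is not None:
            self.spike_prob = np.asarray(self.spike_prob, dtype=float)
            if np.any((self.spike_prob < 0) | (self.spike_prob > 1)):
                raise ParameterError("spike_prob must lie in [0, 1]")


@dataclass
class GReXMatrix:
    """Imputed, column-standardized GReX for one genomic region."""

    values: np.ndarray
    gene_ids: list
    region_id: Optional[str] = None

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        idx = sample_ids if sample_ids is not None else range(self.values.shape[0])
        return pd.DataFrame(self.values, columns=self.gene_ids, index=idx)


def _standardize_columns(Z, drop_degenerate=True, label="SNP"):
    Z = np.asarray(Z, dtype=float)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    keep = sd > 0
    if not drop_degenerate and not keep.all():
        raise DataError(f"zero-variance {label} column cannot be standardized")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance {label} column(s) before fitting",
            stacklevel=3,
        )
    Zs = (Z[:, keep] - mu[keep]) / sd[keep]
    return Zs, keep


def _gibbs_spike_slab_batch(
    x,
    Z,
    iterations,
    burn,
    thin,
    rng,
    fix_pi=None,
    fix_v2=None,
    fix_sigma2=None,
):
    """Gibbs sampler for a batch of independent spike-and-slab regressions.

    Parameters
    ----------
    x : (J, n) expression vectors (centered).
    Z : (J, n, g) standardized genotype blocks.

    Returns a dict of thinned post-burn draws keyed by parameter name.
    """
    x = np.asarray(x, dtype=float)
    Z = np.asarray(Z, dtype=float)
    J, n, g = Z.shape
    ZtZ = np.einsum("jnd,jne->jde", Z, Z)
    Ztx = np.einsum("jnd,jn->jd", Z, x)
    xtx = np.einsum("jn,jn->j", x, x)
    diag = np.einsum("jdd->jd", ZtZ).copy()

    gamma = np.zeros((J, g))
    spike = np.ones((J, g), dtype=bool)  # I_d = 1: spike
    pi = np.full(J, 0.5) if fix_pi is None else np.full(J, float(fix_pi))
    v2 = np.ones(J) if fix_v2 is None else np.full(J, float(fix_v2))
    sigma2 = np.maximum(x.var(axis=1), 1e-8) if fix_sigma2 is None else np.full(J, float(fix_sigma2))
    w = np.zeros((J, g))  # ZtZ @ gamma, maintained incrementally

    n_store = max((iterations - burn + thin - 1) // thin, 0)
    store = {
        "gamma": np.empty((n_store, J, g)),
        "spike": np.empty((n_store, J, g), dtype=bool),
        "sigma2": np.empty((n_store, J)),
        "v2": np.empty((n_store, J)),
        "pi": np.empty((n_store, J)),
    }
    s = 0
    for it in range(iterations):
        for d in range(g):
            t = Ztx[:, d] - w[:, d] + diag[:, d] * gamma[:, d]
            P = diag[:, d] + 1.0 / v2
            log_bf = -0.5 * np.log(v2 * P) + t**2 / (2.0 * sigma2 * P)
            with np.errstate(divide="ignore"):
                log_odds = np.log1p(-pi) - np.log(pi) + log_bf
            p_slab = expit(log_odds)
            slab = rng.random(J) < p_slab
            new = np.where(
                slab,
                t / P + np.sqrt(sigma2 / P) * rng.standard_normal(J),
                0.0,
            )
            delta = new - gamma[:, d]
            gamma[:, d] = new
            spike[:, d] = ~slab
            w += ZtZ[:, :, d] * delta[:, None]

        n_spike = spike.sum(axis=1)
        n_slab = g - n_spike
        if fix_pi is None:
            pi = np.clip(rng.beta(1.0 + n_spike, 1.0 + n_slab), 1e-12, 1 - 1e-12)
        ssq = np.einsum("jd,jd->j", gamma, gamma * ~spike)
        if fix_v2 is None:
            has = n_slab > 0
            if np.any(has):
                shape = n_slab[has] / 2.0
                rate = ssq[has] / (2.0 * sigma2[has])
                v2[has] = np.maximum(rate, 1e-300) / rng.gamma(shape)
                v2 = np.clip(v2, 1e-8, 1e8)
            # with no slab components the Jeffreys conditional is improper: keep current value
        if fix_sigma2 is None:
            rss = xtx - 2.0 * np.einsum("jd,jd->j", gamma, Ztx) + np.einsum("jd,jd->j", gamma, w)
            shape = (n + n_slab) / 2.0
            rate = np.maximum(rss + ssq / v2, 1e-300) / 2.0
            sigma2 = np.clip(rate / rng.gamma(shape), 1e-12, None)

        if it >= burn and (it - burn) % thin == 0:
            store["gamma"][s] = gamma
            store["spike"][s] = spike
            store["sigma2"][s] = sigma2
            store["v2"][s] = v2
            store["pi"][s] = pi
            s += 1
    return store


class SparseExpressionResults:
    """Posterior draws and summaries from :class:`SparseExpressionModel`.

    Attributes
    ----------
    gamma_hat : (g,) posterior-mean SNP effects.
    spike_prob : (g,) posterior probability of the spike (zero) component.
    """

    def __init__(self, model, draws):
        self.model = model
        self.draws = draws
        self.gamma_hat = draws["gamma"].mean(axis=0)[0]
        self.spike_prob = draws["spike"].mean(axis=0)[0]
        self.sigma2_hat = float(draws["sigma2"].mean(axis=0)[0])
        self.v2_hat = float(draws["v2"].mean(axis=0)[0])
        self.pi_hat = float(draws["pi"].mean(axis=0)[0])
        self.n_draws = draws["gamma"].shape[0]

    @property
    def gamma_draws(self):
        return self.draws["gamma"][:, 0, :]

    @property
    def spike_draws(self):
        return self.draws["spike"][:, 0, :]

    def to_weights(self) -> GeneWeights:
        return GeneWeights(
            gene_id=self.model.gene_id,
            snp_ids=list(self.model.snp_ids),
            gamma_hat=self.gamma_hat,
            spike_prob=self.spike_prob,
            sigma2_hat=self.sigma2_hat,
            v2_hat=self.v2_hat,
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": list(self.model.snp_ids),
                "gamma_hat": self.gamma_hat,
                "spike_prob": self.spike_prob,
                "inclusion_prob": 1.0 - self.spike_prob,
            }
        )


class SparseExpressionModel:
    """Bayesian spike-and-slab regression of expression on cis-SNP dosages.

    Parameters
    ----------
    x : (n1,) expression vector for one gene in the reference panel.
    Z : (n1, g) genotype dosages; standardized internally unless
        ``standardize=False`` (in which case columns must already have
        mean 0 and variance 1).
    snp_ids : optional SNP identifiers (default ``snp0..snp{g-1}``).
    """

    def __init__(self, x, Z, snp_ids=None, gene_id="gene", standardize=True):
        x = np.asarray(x, dtype=float)
        Z = np.asarray(Z, dtype=float)
        if x.ndim != 1 or Z.ndim != 2 or Z.shape[0] != x.shape[0]:
            raise ParameterError("x must be (n,) and Z (n, g) with matching n")
        if x.shape[0] < 3:
            raise InsufficientDataError("need at least 3 reference individuals")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(Z)):
            raise DataError("expression and genotypes must be finite")
        if snp_ids is None:
            snp_ids = [f"snp{d}" for d in range(Z.shape[1])]
        if len(snp_ids) != Z.shape[1]:
            raise ParameterError("snp_ids length must match number of SNP columns")
        if standardize:
            Zs, keep = _standardize_columns(Z)
        else:
            Zs, keep = Z, np.ones(Z.shape[1], dtype=bool)
        self.x = x - x.mean()
        self.Z = Zs
        self.snp_ids = [s for s, k in zip(snp_ids, keep) if k]
        self.gene_id = gene_id

    def fit(
        self,
        iterations=4000,
        burn=2000,
        thin=2,
        seed=None,
        fix_pi=None,
        fix_v2=None,
        fix_sigma2=None,
    ) -> SparseExpressionResults:
        if burn >= iterations:
            raise ParameterError("burn must be smaller than iterations")
        rng = np.random.default_rng(seed)
        draws = _gibbs_spike_slab_batch(
            self.x[None, :],
            self.Z[None, :, :],
            iterations,
            burn,
            thin,
            rng,
            fix_pi=fix_pi,
            fix_v2=fix_v2,
            fix_sigma2=fix_sigma2,
        )
        return SparseExpressionResults(self, draws)


def fit_gene_weights(x, Z_ref, snp_ids=None, gene_id="gene", mcmc=None, seed=None) -> GeneWeights:
    """Fit one gene's spike-and-slab model and return its posterior weight summary."""
    mcmc = dict(mcmc or {})
    res = SparseExpressionModel(x, Z_ref, snp_ids=snp_ids, gene_id=gene_id).fit(seed=seed, **mcmc)
    return res.to_weights()


def fit_region_weights(
    expression,
    genotypes,
    gene_ids,
    snp_ids_per_gene,
    mcmc=None,
    seed=None,
) -> list:
    """Fit all genes of a region in one vectorised Gibbs run.

    Parameters
    ----------
    expression : (n1, p) matrix, one column per gene.
    genotypes : sequence of p arrays, each (n1, g_j) standardized dosages.
        All genes must share the same g_j for the batch path; otherwise
        genes are fitted one at a time.
    """
    mcmc = dict(mcmc or {})
    iterations = mcmc.pop("iterations", 4000)
    burn = mcmc.pop("burn", 2000)
    thin = mcmc.pop("thin", 2)
    expression = np.asarray(expression, dtype=float)
    p = expression.shape[1]
    if len(genotypes) != p or len(gene_ids) != p or len(snp_ids_per_gene) != p:
        raise ParameterError("expression columns, genotypes, gene_ids must align")
    sizes = {np.asarray(Z).shape[1] for Z in genotypes}
    if len(sizes) != 1:
        return [
            fit_gene_weights(
                expression[:, j],
                genotypes[j],
                snp_ids=snp_ids_per_gene[j],
                gene_id=gene_ids[j],
                mcmc={"iterations": iterations, "burn": burn, "thin": thin, **mcmc},
                seed=None if seed is None else seed + j,
            )
            for j in range(p)
        ]
    rng = np.random.default_rng(seed)
    x = (expression - expression.mean(axis=0)).T  # (J, n)
    Z = np.stack([np.asarray(Zj, dtype=float) for Zj in genotypes])  # (J, n, g)
    draws = _gibbs_spike_slab_batch(x, Z, iterations, burn, thin, rng, **mcmc)
    gamma_hat = draws["gamma"].mean(axis=0)
    spike_prob = draws["spike"].mean(axis=0)
    sigma2_hat = draws["sigma2"].mean(axis=0)
    v2_hat = draws["v2"].mean(axis=0)
    return [
        GeneWeights(
            gene_id=gene_ids[j],
            snp_ids=list(snp_ids_per_gene[j]),
            gamma_hat=gamma_hat[j],
            spike_prob=spike_prob[j],
            sigma2_hat=float(sigma2_hat[j]),
            v2_hat=float(v2_hat[j]),
        )
        for j in range(p)
    ]


def impute_grex(Z_gwas, weights: Sequence[GeneWeights], snp_ids=None, region_id=None) -> GReXMatrix:
    """Impute and standardize GReX, ``xhat_j = Z_j^G gamma_hat_j``.

    ``Z_gwas`` may be a DataFrame (columns = SNP ids) or an array with
    ``snp_ids`` given separately.  Genes whose posterior-mean weight
    vector is identically zero (or whose imputed column is constant) are
    dropped with a warning, since a constant predictor carries no
    association signal and cannot be standardized.
    """
    if isinstance(Z_gwas, pd.DataFrame):
        snp_index = {s: i for i, s in enumerate(Z_gwas.columns)}
        Z = Z_gwas.to_numpy(dtype=float)
    else:
        if snp_ids is None:
            raise ParameterError("snp_ids required when Z_gwas is not a DataFrame")
        snp_index = {s: i for i, s in enumerate(snp_ids)}
        Z = np.asarray(Z_gwas, dtype=float)
    cols, kept = [], []
    for w in weights:
        if not np.any(w.gamma_hat != 0):
            warnings.warn(f"gene {w.gene_id}: all-zero weights, excluded from GReX", stacklevel=2)
            continue
        try:
            idx = [snp_index[s] for s in w.snp_ids]
        except KeyError as err:
            raise MissingSNPError(w.gene_id, err.args[0]) from err
        col = Z[:, idx] @ w.gamma_hat
        sd = col.std()
        if sd == 0:
            warnings.warn(f"gene {w.gene_id}: constant imputed GReX, excluded", stacklevel=2)
            continue
        cols.append((col - col.mean()) / sd)
        kept.append(w.gene_id)
    values = np.column_stack(cols) if cols else np.empty((Z.shape[0], 0))
    return GReXMatrix(values=values, gene_ids=kept, region_id=region_id)


_REQUIRED_COLS = ("gene", "rsid", "weight")


def write_weights(weights: Sequence[GeneWeights], path) -> None:
    """Write weights as TSV with columns gene, rsid, weight[, spike_prob, ...]."""
    rows = []
    for w in weights:
        for d, (snp, g) in enumerate(zip(w.snp_ids, w.gamma_hat)):
            row = {"gene": w.gene_id, "rsid": snp, "weight": g}
            if w.spike_prob is not None:
                row["spike_prob"] = w.spike_prob[d]
            for key, vals in w.extra.items():
                row[key] = vals[d]
            rows.append(row)
    cols = list(_REQUIRED_COLS)
    if any(w.spike_prob is not None for w in weights):
        cols.append("spike_prob")
    extra_cols = sorted({k for w in weights for k in w.extra})
    pd.DataFrame(rows, columns=cols + extra_cols).to_csv(path, sep="\t", index=False)


def read_weights(path) -> list:
    """Read a weight TSV written by :func:`write_weights` (or compatible)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "rsid": str})
    except pd.errors.EmptyDataError as err:
        raise FormatError(f"{path}: empty or malformed weight file") from err
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: line 1: missing required column(s) {missing}")
    if len(df) == 0:
        return []
    dup = df.duplicated(subset=["gene", "rsid"])
    if dup.any():
        first = df[dup].iloc[0]
        raise FormatError(f"{path}: duplicated (gene, rsid) row: ({first['gene']}, {first['rsid']})")
    extra_cols = [c for c in df.columns if c not in (*_REQUIRED_COLS, "spike_prob")]
    out = []
    for gene, grp in df.groupby("gene", sort=False):
        out.append(
            GeneWeights(
                gene_id=str(gene),
                snp_ids=list(grp["rsid"]),
                gamma_hat=grp["weight"].to_numpy(dtype=float),
                spike_prob=grp["spike_prob"].to_numpy(dtype=float) if "spike_prob" in df else None,
                extra={c: list(grp[c]) for c in extra_cols},
            )
        )
    return out
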