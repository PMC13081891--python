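"""Region screening: univariate TWAS, Fisher meta-analysis, LD-block selection.

Before joint fine mapping, candidate LD blocks are screened by running a
univariate TWAS of every gene against every phenotype, combining each
gene's p-values across phenotypes with Fisher's method, and keeping the
blocks that contain at least one gene passing a genome-wide threshold.
Because phenotypes are correlated, the combined p-values are screening
scores rather than calibrated tests; they only rank regions for the joint
model, which does its own inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DataError, ParameterError

__all__ = [
    "TWASResults",
    "RegionSet",
    "univariate_twas",
    "twas_scan",
    "fisher_combine",
    "select_regions",
]

logger = logging.getLogger(__name__)


@dataclass
class TWASResults:
    """Gene x phenotype matrix of univariate TWAS p-values."""

    pvalues: pd.DataFrame            # rows = genes, columns = phenotypes

    def __post_init__(self):
        vals = self.pvalues.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals > 0) & (vals <= 1))
        if not ok.all():
            raise DataError("p-values must lie in (0, 1] (NaN allowed for non-convergence)")

    @property
    def gene_ids(self):
        return list(self.pvalues.index)

    @property
    def phenotype_ids(self):
        return list(self.pvalues.columns)


@dataclass
class RegionSet:
    """LD blocks (BED convention: 0-based, half-open) and their gene content."""

    blocks: pd.DataFrame             # columns: chrom, start, end, block_id
    gene_to_block: dict              # gene -> block_id
    selected_blocks: list = field(default_factory=list)
    genes_per_selected: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"chrom", "start", "end", "block_id"}
        if not req.issubset(self.blocks.columns):
            raise ParameterError(f"blocks must have columns {sorted(req)}")
        for chrom, grp in self.blocks.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ParameterError(f"overlapping blocks on {chrom}")


def univariate_twas(grex_col, y, outcome_type, covariates=None):
    """Wald p-value of one gene's GReX against one outcome.

    Continuous outcomes use OLS (exact t test), binary use logistic
    regression, counts use negative-binomial regression.  Non-convergence
    or separation yields NaN with a warning rather than an error.
    """
    x = np.asarray(grex_col, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ParameterError("grex and outcome lengths differ")
    X = x[:, None]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ParameterError("covariate matrix is rank deficient")
        X = np.column_stack([X, C])
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if outcome_type == "continuous":
                fit = sm.OLS(y, X).fit()
            elif outcome_type == "binary":
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            elif outcome_type == "count":
                fit = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            else:
                raise ParameterError(f"unknown outcome type {outcome_type!r}")
        if not getattr(fit, "mle_retvals", {"converged": True}).get("converged", True):
            raise ValueError("maximum-likelihood fit did not converge (possible separation)")
        p = float(fit.pvalues[1])
        if not np.isfinite(p):
            raise ValueError("non-finite p-value")
        return min(max(p, np.finfo(float).tiny), 1.0)
    except ParameterError:
        raise
    except Exception as err:  # separation / non-convergence
        warnings.warn(f"TWAS model did not converge ({err}); p set to NaN", stacklevel=2)
        return float("nan")


def twas_scan(grex, phenotypes, gene_ids=None, covariates=None) -> TWASResults:
    """Univariate TWAS of every gene against every phenotype."""
    from .simulate import PhenotypeTable

    if isinstance(phenotypes, PhenotypeTable):
        Y, types, ph_ids = phenotypes.values, phenotypes.types, phenotypes.ids
    else:
        raise ParameterError("phenotypes must be a PhenotypeTable")
    if hasattr(grex, "values") and hasattr(grex, "gene_ids"):
        gene_ids = gene_ids or list(grex.gene_ids)
        grex = grex.values
    grex = np.asarray(grex, dtype=float)
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene{j}" for j in range(grex.shape[1])]
    out = np.empty((len(gene_ids), len(ph_ids)))
    for k, tk in enumerate(types):
        for j in range(len(gene_ids)):
            out[j, k] = univariate_twas(grex[:, j], Y[:, k], tk, covariates=covariates)
    return TWASResults(pvalues=pd.DataFrame(out, index=gene_ids, columns=ph_ids))


def fisher_combine(pvals) -> float:
    """Fisher's method: -2 sum(log p) against a chi-square with 2q df (upper tail)."""
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        return float("nan")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    stat = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(stat, 2 * p.size))


def select_regions(twas: TWASResults, blocks: RegionSet, threshold=1e-8) -> RegionSet:
    """Blocks containing at least one gene with Fisher-combined p below threshold."""
    if not 0 < threshold < 1:
        raise ParameterError("threshold must lie in (0, 1)")
    combined = {
        g: fisher_combine(twas.pvalues.loc[g].to_numpy()) for g in twas.gene_ids
    }
    missing = [g for g in twas.gene_ids if g not in blocks.gene_to_block]
    if missing:
        raise ParameterError(f"genes not mapped to any block: {missing[:5]}")
    hits = {}
    for g, p in combined.items():
        if not np.isnan(p) and p < threshold:
            hits.setdefault(blocks.gene_to_block[g], []).append(g)
    selected = sorted(hits)
    logger.info("selected %d of %d blocks at Fisher p < %g", len(selected), len(blocks.blocks), threshold)
    genes_per = {
        b: sorted(g for g, bb in blocks.gene_to_block.items() if bb == b) for b in selected
    }
    return RegionSet(
        blocks=blocks.blocks,
        gene_to_block=blocks.gene_to_block,
        selected_blocks=selected,
        genes_per_selected=genes_per,
    )
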