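"""Synthetic reference-panel and GWAS data with known causal structure.

The generator emulates a phenome-wide TWAS design: standardized genotypes
with tunable AR(1) linkage disequilibrium, a sparse cis-eQTL architecture
(10 cis-SNPs per gene by default), contiguous genomic regions of 10 genes,
and many correlated phenotypes driven by a small number of latent factors
whose signal comes from the genetically regulated expression (GReX) of a
few causal genes per region.

Three scenarios are supported:

* ``homogeneous`` — every latent factor shares the same causal genes;
* ``heterogeneous`` — causal genes differ across factors;
* ``null`` — no causal genes (all gene effects zero).

Heritability ``h2`` is the fraction of each phenotype's variance explained
by GReX, enforced exactly on the observed scale for continuous phenotypes
and on the latent linear-predictor scale for binary/count phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .exceptions import DataError, ParameterError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "GenotypePanel",
    "PhenotypeTable",
    "SyntheticStudy",
    "mixed_type_map",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_study",
    "realized_grex_fractions",
]

SCENARIOS = ("homogeneous", "heterogeneous", "null")


def mixed_type_map(q: int) -> list:
    """Even continuous/binary/count split over ``q`` phenotype columns."""
    kinds = ["continuous", "binary", "count"]
    return [kinds[min(3 * k // q, 2)] for k in range(q)]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the simulation design the method was evaluated under:
    a reference panel of n1=250, GWAS cohort of n2=5000, 10 regions of 10
    genes with 10 cis-SNPs each, q=50 phenotypes from m in {1,3,5} latent
    factors, and heritability h2 in {1%, 3%, 5%}.
    """

    scenario: str = "homogeneous"
    n1: int = 250
    n2: int = 5000
    n_regions: int = 10
    genes_per_region: int = 10
    snps_per_gene: int = 10
    q: int = 50
    m: int = 3
    h2: float = 0.05
    h2_expr: float = 0.3
    n_causal_snps: int = 3
    ld_rho: float = 0.5
    maf_range: tuple = (0.05, 0.5)
    causal_per_region: tuple = (1, 2)  # per-region causal count drawn uniformly from this range
    type_mix: Optional[Sequence[str]] = None  # per-column types; None = all continuous
    nb_r: float = 5.0
    count_intercept: float = -1.5
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"scenario must be one of {SCENARIOS}")
        for name in ("n1", "n2", "n_regions", "genes_per_region", "snps_per_gene", "q", "m"):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 0.0 < self.h2 < 1.0:
            raise ParameterError("h2 must lie in (0, 1)")
        if not 0.0 <= self.h2_expr < 1.0:
            raise ParameterError("h2_expr must lie in [0, 1)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ParameterError("ld_rho must lie in [0, 1)")
        if self.q < self.m:
            raise ParameterError("q must be at least the number of factors m")
        if self.type_mix is not None:
            if len(self.type_mix) != self.q:
                raise ParameterError("type_mix must give a type per phenotype column")
            bad = set(self.type_mix) - {"continuous", "binary", "count"}
            if bad:
                raise ParameterError(f"unknown phenotype types: {sorted(bad)}")
        if self.scenario == "heterogeneous" and self.m == 1:
            warnings.warn(
                "heterogeneous causality with m=1 degenerates to the homogeneous scenario",
                stacklevel=2,
            )

    @property
    def p_total(self) -> int:
        return self.n_regions * self.genes_per_region

    @property
    def phenotype_types(self) -> list:
        return list(self.type_mix) if self.type_mix is not None else ["continuous"] * self.q


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic study."""

    true_gamma: list                 # per-gene cis-SNP effect vectors (reference scale)
    causal_sets: list                # per-factor sets of causal gene indices
    true_B: np.ndarray               # p_total x m gene-by-factor effects
    true_Lambda: np.ndarray          # q x m loadings with known zero pattern
    true_F: np.ndarray               # n2 x m factor scores
    genetic_part: np.ndarray         # n2 x q GReX-driven component of each linear predictor
    latent_pred: np.ndarray          # n2 x q full latent linear predictor
    tau2: np.ndarray                 # q residual variances used on the latent scale

    @property
    def causal_genes(self) -> set:
        out = set()
        for s in self.causal_sets:
            out |= set(s)
        return out


@dataclass
class GenotypePanel:
    """Standardized dosage matrix with SNP annotations."""

    values: np.ndarray               # n x G, column-standardized dosages
    snp_ids: list
    maf: np.ndarray
    role: str = "reference"

    def to_frame(self, sample_prefix="s") -> pd.DataFrame:
        idx = [f"{sample_prefix}{i}" for i in range(self.values.shape[0])]
        return pd.DataFrame(self.values, columns=self.snp_ids, index=idx)


@dataclass
class PhenotypeTable:
    """Outcome matrix with a per-column data-type tag."""

    values: np.ndarray
    types: list
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.types):
            raise ParameterError("phenotype values must be n x q with one type per column")
        if not self.ids:
            self.ids = [f"ph{k:03d}" for k in range(self.values.shape[1])]

    def to_frame(self, sample_prefix="s") -> pd.DataFrame:
        idx = [f"{sample_prefix}{i}" for i in range(self.values.shape[0])]
        return pd.DataFrame(self.values, columns=self.ids, index=idx)


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    ref_genotypes: GenotypePanel
    ref_expression: np.ndarray       # n1 x p_total
    gwas_genotypes: GenotypePanel
    grex_true: np.ndarray            # n2 x p_total standardized true genetic expression
    phenotypes: PhenotypeTable
    truth: SimulationTruth
    gene_ids: list
    gene_map: pd.DataFrame           # columns: gene, region, snps (comma-joined)


def _rng_from(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def simulate_genotypes(n, g, ld_rho, maf_range=(0.05, 0.5), seed=None, maf=None, rng=None):
    """Standardized dosages from a thresholded latent AR(1) Gaussian.

    Two independent latent haplotypes are generated per individual, each an
    AR(1) Gaussian with lag-1 correlation ``ld_rho`` across adjacent SNPs;
    each is thresholded at the per-SNP minor-allele-frequency quantile and
    the two alleles summed to a dosage in {0, 1, 2}, then column
    standardized.

    Returns ``(Z, maf)`` where ``maf`` are the per-SNP frequencies (drawn
    uniformly from ``maf_range`` unless supplied, so reference and GWAS
    panels can share them).
    """
    if not np.isfinite(ld_rho) or not 0.0 <= ld_rho < 1.0:
        raise ParameterError("ld_rho must lie in [0, 1)")
    if n < 2 or g < 1:
        raise ParameterError("need n >= 2 individuals and g >= 1 SNPs")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = _rng_from(seed, rng)
    if maf is None:
        maf = rng.uniform(lo, hi, size=g)
    else:
        maf = np.asarray(maf, dtype=float)
        if maf.shape != (g,) or np.any((maf <= 0) | (maf > 0.5)):
            raise ParameterError("maf must be length g with entries in (0, 0.5]")
    thresh = norm.ppf(1.0 - maf)

    def _haplotype():
        lat = np.empty((n, g))
        lat[:, 0] = rng.standard_normal(n)
        if g > 1:
            innov = rng.standard_normal((n, g - 1)) * np.sqrt(1.0 - ld_rho**2)
            for d in range(1, g):
                lat[:, d] = ld_rho * lat[:, d - 1] + innov[:, d - 1]
        return lat > thresh

    dosage = (_haplotype() + _haplotype()).astype(float)
    for _ in range(10):  # re-draw monomorphic columns (possible at small n, low MAF)
        sd = dosage.std(axis=0)
        bad = sd == 0
        if not bad.any():
            break
        k = int(bad.sum())
        redraw = (rng.random((n, k)) < maf[bad]).astype(float) + (
            rng.random((n, k)) < maf[bad]
        )
        dosage[:, bad] = redraw
    sd = dosage.std(axis=0)
    if np.any(sd == 0):
        raise DataError("monomorphic SNP column persisted after re-draws; increase n or MAF")
    Z = (dosage - dosage.mean(axis=0)) / sd
    return Z, maf


def simulate_expression(Z_ref, n_causal_snps, h2_expr, seed=None, rng=None):
    """One gene's reference expression from a sparse cis-eQTL architecture.

    Effects of ``n_causal_snps`` randomly placed causal SNPs are drawn
    N(0, 1) and rescaled so the sample variance of ``Z gamma`` equals
    ``h2_expr``; residual noise has variance ``1 - h2_expr``.
    Returns ``(x, gamma)``.
    """
    Z = np.asarray(Z_ref, dtype=float)
    n, g = Z.shape
    if not 0.0 <= h2_expr < 1.0:
        raise ParameterError("h2_expr must lie in [0, 1)")
    if n_causal_snps < 0 or n_causal_snps > g:
        raise ParameterError("n_causal_snps must lie in [0, g]")
    if h2_expr > 0 and n_causal_snps == 0:
        raise ParameterError("h2_expr > 0 requires at least one causal SNP")
    rng = _rng_from(seed, rng)
    gamma = np.zeros(g)
    if h2_expr > 0:
        idx = rng.choice(g, size=n_causal_snps, replace=False)
        gamma[idx] = rng.standard_normal(n_causal_snps)
        s = np.var(Z @ gamma)
        if s == 0:  # pathological draw (all effects ~0); retry once deterministically
            gamma[idx] = np.abs(rng.standard_normal(n_causal_snps)) + 0.1
            s = np.var(Z @ gamma)
        gamma *= np.sqrt(h2_expr / s)
    x = Z @ gamma + rng.standard_normal(n) * np.sqrt(1.0 - h2_expr)
    return x, gamma


def _assign_causal_sets(cfg: SimulationConfig, rng) -> list:
    """Per-factor causal gene index sets C_l, following the scenario contract."""
    if cfg.scenario == "null":
        return [set() for _ in range(cfg.m)]
    lo, hi = cfg.causal_per_region
    causal = []
    for r in range(cfg.n_regions):
        k = int(rng.integers(lo, hi + 1))
        genes = rng.choice(cfg.genes_per_region, size=k, replace=False)
        causal.extend(r * cfg.genes_per_region + genes)
    causal = sorted(int(j) for j in causal)
    if cfg.scenario == "homogeneous" or cfg.m == 1:
        return [set(causal) for _ in range(cfg.m)]
    # heterogeneous: each causal gene drives exactly one factor; round-robin over a
    # shuffled factor order guarantees every factor receives a gene and the sets differ
    order = rng.permutation(cfg.m)
    sets = [set() for _ in range(cfg.m)]
    for i, j in enumerate(rng.permutation(causal)):
        sets[order[i % cfg.m]].add(int(j))
    return sets


def _assign_loading_support(cfg: SimulationConfig, rng) -> list:
    """Factor indices each phenotype loads on (1 or 2 factors per phenotype)."""
    support = []
    for k in range(cfg.q):
        if k < cfg.m:  # guarantee every factor has at least one phenotype
            base = k
        else:
            base = int(rng.integers(cfg.m))
        if cfg.m > 1 and rng.random() < 0.5:
            other = int(rng.integers(cfg.m - 1))
            other = other + (other >= base)
            support.append(sorted((base, other)))
        else:
            support.append([base])
    return support


def simulate_phenotypes(grex, config: SimulationConfig, rng=None):
    """Generate factors, loadings and mixed-type phenotypes from GReX.

    ``grex`` is the n2 x p matrix of standardized true genetic expression
    components.  Returns ``(PhenotypeTable, SimulationTruth)`` (with
    ``true_gamma`` left empty; :func:`simulate_study` fills it in).
    """
    rng = _rng_from(config.seed, rng)
    grex = np.asarray(grex, dtype=float)
    n2, p = grex.shape
    if p != config.p_total:
        raise ParameterError("grex has wrong number of gene columns for this config")
    m, q, h2 = config.m, config.q, config.h2
    types = config.phenotype_types

    causal_sets = _assign_causal_sets(config, rng)
    v_g = 0.0 if config.scenario == "null" else min(3.0 * h2, 0.9)

    B = np.zeros((p, m))
    G = np.zeros((n2, m))  # genetic part of each factor
    for l, C in enumerate(causal_sets):
        if C:
            idx = sorted(C)
            b = rng.standard_normal(len(idx))
            gl = grex[:, idx] @ b
            b *= np.sqrt(v_g / max(np.var(gl), 1e-12))
            B[idx, l] = b
            G[:, l] = grex[:, idx] @ b
    F = G + rng.standard_normal((n2, m)) * np.sqrt(max(1.0 - v_g, 1e-12))

    support = _assign_loading_support(config, rng)
    Lam = np.zeros((q, m))
    for k, sup in enumerate(support):
        lam = rng.standard_normal(len(sup))
        lam /= np.linalg.norm(lam)
        Lam[k, sup] = lam

    genetic_part = G @ Lam.T          # n2 x q
    factor_part = F @ Lam.T
    tau2 = np.empty(q)
    latent = np.empty((n2, q))
    Y = np.empty((n2, q))
    for k in range(q):
        if config.scenario == "null":
            tau2[k] = 2.0  # matches the non-null noise magnitude for a 1-factor phenotype
        else:
            # residual variance solved so the phenotype's GReX-explained fraction is h2
            tau2[k] = max(np.var(genetic_part[:, k]) / h2 - np.var(factor_part[:, k]), 0.05)
        eps = rng.standard_normal(n2) * np.sqrt(tau2[k])
        zeta = factor_part[:, k] + eps
        if types[k] == "continuous":
            latent[:, k] = zeta
            Y[:, k] = zeta
        elif types[k] == "binary":
            latent[:, k] = zeta
            Y[:, k] = rng.random(n2) < expit(zeta)
        else:  # count: negative binomial with mean nb_r * exp(zeta + intercept)
            zc = zeta + config.count_intercept
            latent[:, k] = zc
            Y[:, k] = rng.negative_binomial(config.nb_r, expit(-zc))

    truth = SimulationTruth(
        true_gamma=[],
        causal_sets=causal_sets,
        true_B=B,
        true_Lambda=Lam,
        true_F=F,
        genetic_part=genetic_part,
        latent_pred=latent,
        tau2=tau2,
    )
    return PhenotypeTable(values=Y, types=types), truth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full reference-panel + GWAS study for one scenario."""
    rng = np.random.default_rng(config.seed)
    T, pt, gj = config.n_regions, config.genes_per_region, config.snps_per_gene

    ref_blocks, gwas_blocks, mafs = [], [], []
    snp_ids, gene_ids, map_rows = [], [], []
    for r in range(T):
        G = pt * gj
        Zr, maf = simulate_genotypes(config.n1, G, config.ld_rho, config.maf_range, rng=rng)
        Zg, _ = simulate_genotypes(config.n2, G, config.ld_rho, config.maf_range, maf=maf, rng=rng)
        ref_blocks.append(Zr)
        gwas_blocks.append(Zg)
        mafs.append(maf)
        for j in range(pt):
            gene = f"r{r:02d}g{j:02d}"
            gene_ids.append(gene)
            snps = [f"{gene}s{d:02d}" for d in range(gj)]
            snp_ids.extend(snps)
            map_rows.append({"gene": gene, "region": f"r{r:02d}", "snps": ",".join(snps)})

    p = config.p_total
    ref_expr = np.empty((config.n1, p))
    grex = np.empty((config.n2, p))
    gammas = []
    for r in range(T):
        for j in range(pt):
            sl = slice(j * gj, (j + 1) * gj)
            x, gamma = simulate_expression(
                ref_blocks[r][:, sl], config.n_causal_snps, config.h2_expr, rng=rng
            )
            jj = r * pt + j
            ref_expr[:, jj] = x
            gammas.append(gamma)
            xg = gwas_blocks[r][:, sl] @ gamma
            sd = xg.std()
            grex[:, jj] = (xg - xg.mean()) / sd if sd > 0 else 0.0

    phenotypes, truth = simulate_phenotypes(grex, config, rng=rng)
    truth.true_gamma = gammas

    ref_panel = GenotypePanel(
        values=np.hstack(ref_blocks), snp_ids=snp_ids, maf=np.concatenate(mafs), role="reference"
    )
    gwas_panel = GenotypePanel(
        values=np.hstack(gwas_blocks), snp_ids=snp_ids, maf=np.concatenate(mafs), role="gwas"
    )
    return SyntheticStudy(
        config=config,
        ref_genotypes=ref_panel,
        ref_expression=ref_expr,
        gwas_genotypes=gwas_panel,
        grex_true=grex,
        phenotypes=phenotypes,
        truth=truth,
        gene_ids=gene_ids,
        gene_map=pd.DataFrame(map_rows),
    )


def realized_grex_fractions(phenotypes: PhenotypeTable, truth: SimulationTruth) -> np.ndarray:
    """Per-phenotype realized GReX-explained variance fraction.

    Continuous columns use the observed scale var(G_k)/var(y_k); discrete
    columns use the latent linear-predictor scale var(G_k)/var(zeta_k).
    """
    q = phenotypes.values.shape[1]
    out = np.empty(q)
    for k in range(q):
        num = np.var(truth.genetic_part[:, k])
        if phenotypes.types[k] == "continuous":
            den = np.var(phenotypes.values[:, k])
        else:
            den = np.var(truth.latent_pred[:, k])
        out[k] = num / den if den > 0 else 0.0
    return out
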