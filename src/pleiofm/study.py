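"""End-to-end simulation-study driver.

Runs the full pipeline on synthetic studies — train expression weights on
the reference panel, impute GReX into the GWAS cohort, fine-map every
region with the joint model, pool posterior inclusion probabilities across
regions — and scores the result against the known truth (ROC AUC of the
omnibus PIPs, true/false positives under BFDR control, and an F-score for
recovery of the sparse loading support).

Chain lengths here default to a desk-scale analysis profile suited to the
reduced problem sizes this driver generates; the model's own defaults
remain the long chains appropriate for real analyses.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .expression import fit_region_weights, impute_grex
from .model import ChainConfig, GeneFactorFineMapper
from .select import align_draws, bfdr_select, compute_pips, _greedy_match
from .simulate import SimulationConfig, SyntheticStudy, mixed_type_map, simulate_study

__all__ = [
    "StudyProfile",
    "ReplicateResult",
    "auc_score",
    "loading_fscore",
    "run_replicate",
    "run_simulation_study",
    "null_fdp_study",
]

logger = logging.getLogger(__name__)

#: Desk-scale analysis profile: short warm-started chains with a capped
#: factor truncation, sized for the reduced simulation dimensions.
DESK_CHAIN = dict(iterations=220, burn=120, thin=1, m_init=6, m_max=6, pg_trunc=6)
DESK_WEIGHT_MCMC = dict(iterations=800, burn=400, thin=2)


@dataclass
class StudyProfile:
    """Problem sizes and chain settings for one simulation-study run."""

    n1: int = 250
    n2: int = 1000
    n_regions: int = 5
    q: int = 20
    mixed: bool = False
    chain: dict = field(default_factory=lambda: dict(DESK_CHAIN))
    weight_mcmc: dict = field(default_factory=lambda: dict(DESK_WEIGHT_MCMC))
    alpha: float = 0.1

    def make_config(self, scenario, m, h2, seed) -> SimulationConfig:
        return SimulationConfig(
            scenario=scenario,
            n1=self.n1,
            n2=self.n2,
            n_regions=self.n_regions,
            q=self.q,
            m=m,
            h2=h2,
            type_mix=mixed_type_map(self.q) if self.mixed else None,
            seed=seed,
        )


@dataclass
class ReplicateResult:
    pips: np.ndarray                 # pooled omnibus PIPs over all genes
    pip_factor: list                 # per-region factor PIP matrices
    truth_labels: np.ndarray         # 1 = causal gene
    selected: np.ndarray             # indices selected at BFDR alpha
    auc: float
    tp: int
    fp: int
    fdp: float
    loading_f1: Optional[float]
    n_genes: int
    runtime: float


def auc_score(scores, labels) -> float:
    """ROC AUC of PIPs against ground truth (NaN when only one class present)."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def loading_fscore(draws_list, truth, eps=1e-2, prob=0.5) -> Optional[float]:
    """F-score for recovery of the true sparse loading support.

    A loading is called nonzero when its posterior probability of exceeding
    ``eps`` in absolute value is above ``prob``.  Estimated factor columns
    are greedily matched to the true loading columns (by absolute inner
    product of the posterior-mean loadings) before comparing supports; with
    several regions the per-region estimates are OR-combined, since each
    region's model sees the same phenotype factor space.
    """
    true_support = truth.true_Lambda != 0
    q, m_true = true_support.shape
    if not true_support.any():
        return None
    est_any = np.zeros((q, m_true), dtype=bool)
    for draws in draws_list:
        _, _, Lam = align_draws(draws)
        lam_mean = Lam.mean(axis=0)
        nz = (np.abs(Lam) > eps).mean(axis=0) > prob     # (q, m_est)
        m_est = lam_mean.shape[1]
        k = min(m_true, m_est)
        ref = truth.true_Lambda
        if m_est < m_true:
            ref = ref[:, :m_est]
        perm, _ = _greedy_match(ref, lam_mean)
        est_any[:, :k] |= nz[:, perm[:k]]
    tp = int((est_any & true_support).sum())
    fp = int((est_any & ~true_support).sum())
    fn = int((~est_any & true_support).sum())
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return float(2 * prec * rec / (prec + rec))


def run_replicate(
    study: SyntheticStudy,
    chain: Optional[dict] = None,
    weight_mcmc: Optional[dict] = None,
    alpha: float = 0.1,
    seed: Optional[int] = None,
) -> ReplicateResult:
    """Full pipeline on one synthetic study; scores pooled over regions."""
    t0 = time.time()
    cfg = study.config
    chain = dict(DESK_CHAIN, **(chain or {}))
    weight_mcmc = dict(DESK_WEIGHT_MCMC, **(weight_mcmc or {}))
    rng = np.random.default_rng(seed)
    pt, gj = cfg.genes_per_region, cfg.snps_per_gene

    pips_all, labels_all = [], []
    pip_factor, draws_list = [], []
    for r in range(cfg.n_regions):
        jlo = r * pt
        genes = study.gene_ids[jlo : jlo + pt]
        snp_lists = [study.gene_map.iloc[jlo + j]["snps"].split(",") for j in range(pt)]
        snp_index = {s: i for i, s in enumerate(study.ref_genotypes.snp_ids)}
        Zr = [study.ref_genotypes.values[:, [snp_index[s] for s in sl]] for sl in snp_lists]
        weights = fit_region_weights(
            study.ref_expression[:, jlo : jlo + pt],
            Zr,
            genes,
            snp_lists,
            mcmc=weight_mcmc,
            seed=int(rng.integers(2**31 - 1)),
        )
        snp_index_g = {s: i for i, s in enumerate(study.gwas_genotypes.snp_ids)}
        region_snps = [s for sl in snp_lists for s in sl]
        Zg = study.gwas_genotypes.values[:, [snp_index_g[s] for s in region_snps]]
        grex = impute_grex(Zg, weights, snp_ids=region_snps, region_id=f"r{r:02d}")
        if grex.values.shape[1] == 0:
            logger.warning("region %d: no imputable genes; all PIPs set to 0", r)
            pips_all.append(np.zeros(pt))
            labels_all.append(
                np.isin(np.arange(jlo, jlo + pt), sorted(study.truth.causal_genes)).astype(int)
            )
            continue
        fm = GeneFactorFineMapper(
            study.phenotypes,
            grex=grex,
            config=ChainConfig(**chain),
        )
        res = fm.fit(seed=int(rng.integers(2**31 - 1)))
        pips = compute_pips(res.draws)
        draws_list.append(res.draws)
        pip_factor.append(pips.pip_factor)
        # genes dropped at imputation get PIP 0
        full = np.zeros(pt)
        kept = {g: i for i, g in enumerate(grex.gene_ids)}
        for j, g in enumerate(genes):
            if g in kept:
                full[j] = pips.pip_omnibus[kept[g]]
        pips_all.append(full)
        labels_all.append(
            np.isin(np.arange(jlo, jlo + pt), sorted(study.truth.causal_genes)).astype(int)
        )

    pips = np.concatenate(pips_all)
    labels = np.concatenate(labels_all)
    sel, _, _ = bfdr_select(pips, alpha)
    tp = int(labels[sel].sum())
    fp = int(len(sel) - tp)
    fdp = fp / max(len(sel), 1)
    return ReplicateResult(
        pips=pips,
        pip_factor=pip_factor,
        truth_labels=labels,
        selected=sel,
        auc=auc_score(pips, labels),
        tp=tp,
        fp=fp,
        fdp=float(fdp),
        loading_f1=loading_fscore(draws_list, study.truth),
        n_genes=len(pips),
        runtime=time.time() - t0,
    )


def run_simulation_study(
    scenario="homogeneous",
    factors=(1, 3, 5),
    heritabilities=(0.01, 0.03, 0.05),
    replicates=20,
    seed=0,
    profile: Optional[StudyProfile] = None,
) -> pd.DataFrame:
    """Replicated grid study; one row of aggregated metrics per (m, h2) cell."""
    profile = profile or StudyProfile()
    rows = []
    ss = np.random.SeedSequence(seed)
    for m in factors:
        for h2 in heritabilities:
            stats = []
            for rep in range(replicates):
                child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
                cfg = profile.make_config(scenario, m, h2, child)
                try:
                    study = simulate_study(cfg)
                    res = run_replicate(
                        study,
                        chain=profile.chain,
                        weight_mcmc=profile.weight_mcmc,
                        alpha=profile.alpha,
                        seed=child + 1,
                    )
                    stats.append(res)
                except Exception as err:  # pragma: no cover - defensive
                    logger.warning("replicate %d (m=%d, h2=%g) failed: %s", rep, m, h2, err)
            if not stats:
                continue
            aucs = np.array([s.auc for s in stats], dtype=float)
            f1s = np.array([np.nan if s.loading_f1 is None else s.loading_f1 for s in stats])
            rows.append(
                {
                    "scenario": scenario,
                    "m": m,
                    "h2": h2,
                    "replicates": len(stats),
                    "auc_mean": np.nanmean(aucs) if np.any(~np.isnan(aucs)) else np.nan,
                    "auc_se": np.nanstd(aucs) / np.sqrt(max(np.sum(~np.isnan(aucs)), 1)),
                    "tp_mean": np.mean([s.tp for s in stats]),
                    "fp_mean": np.mean([s.fp for s in stats]),
                    "fdp_mean": np.mean([s.fdp for s in stats]),
                    "loading_f1_mean": np.nanmean(f1s) if np.any(~np.isnan(f1s)) else np.nan,
                    "runtime_mean": np.mean([s.runtime for s in stats]),
                }
            )
    return pd.DataFrame(rows)


def null_fdp_study(replicates=50, seed=1, profile: Optional[StudyProfile] = None, alpha=0.1):
    """Empirical false-discovery proportion under the global null.

    Simulates the null scenario (no causal genes) ``replicates`` times with
    mixed-type phenotypes, runs the full pipeline, selects genes by omnibus
    BFDR at ``alpha``, and returns ``(mean FDP, per-replicate FDPs)`` —
    under the null every selected gene is a false positive.
    """
    profile = profile or StudyProfile(mixed=True)
    fdps = []
    for rep in range(replicates):
        rep_seed = int((seed * 1_000_003 + rep) % (2**31 - 1))
        cfg = profile.make_config("null", m=3, h2=0.05, seed=rep_seed)
        study = simulate_study(cfg)
        res = run_replicate(
            study,
            chain=profile.chain,
            weight_mcmc=profile.weight_mcmc,
            alpha=alpha,
            seed=rep_seed + 1,
        )
        fdps.append(res.fdp)
        logger.info("null replicate %d: %d selected (FDP %.2f)", rep, len(res.selected), res.fdp)
    return float(np.mean(fdps)), np.array(fdps)
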