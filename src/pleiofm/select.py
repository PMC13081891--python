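"""Posterior inclusion probabilities and Bayesian FDR gene selection.

A gene j is "in" the model for factor l whenever ``I_j U_jl = 1``; the
factor-specific posterior inclusion probability is the posterior mass of
that event, ``PIP_jl = P(beta_jl != 0 | data)``, and the omnibus PIP is
the union over factors, ``PIP_j = P(U_l {beta_jl != 0} | data)``.  Genes
are selected by thresholding PIPs at the smallest value z* whose Bayesian
false discovery rate — the average of (1 - PIP) over the selected set
{j : PIP_j >= z*} — stays at or below a nominal level alpha.

Factor-indexed summaries are computed on draws aligned to a reference
loading matrix (greedy column matching with sign flips), since factor
label and sign are not identified; the omnibus PIP is label-invariant and
is computed on the raw draws.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "PIPTable",
    "SelectionResult",
    "align_draws",
    "aligned_loading_mean",
    "compute_pips",
    "bfdr",
    "bfdr_select",
    "select_genes",
    "report",
]


@dataclass
class PIPTable:
    pip_factor: np.ndarray           # (p, m)
    pip_omnibus: np.ndarray          # (p,)
    n_draws: int

    def __post_init__(self):
        if np.any((self.pip_factor < 0) | (self.pip_factor > 1)):
            raise ParameterError("factor PIPs must lie in [0, 1]")
        if np.any(self.pip_omnibus + 1e-12 < self.pip_factor.max(axis=1)):
            raise ParameterError("omnibus PIP cannot be below any factor PIP")


@dataclass
class SelectionResult:
    selected_genes: list
    selected_idx: np.ndarray
    threshold: float                 # z*
    bfdr_at_threshold: float
    alpha: float
    factor_targets: dict = field(default_factory=dict)   # gene -> list of factor indices
    loading_summary: pd.DataFrame | None = None
    mode: str = "omnibus"


def _greedy_match(ref: np.ndarray, lam: np.ndarray):
    """Permutation and signs aligning columns of ``lam`` to ``ref`` by |inner product|."""
    m = ref.shape[1]
    M = ref.T @ lam                  # (m_ref, m_draw)
    perm = np.full(m, -1, dtype=int)
    signs = np.ones(m)
    A = np.abs(M).copy()
    for _ in range(m):
        i, j = np.unravel_index(np.argmax(A), A.shape)
        perm[i] = j
        signs[i] = 1.0 if M[i, j] >= 0 else -1.0
        A[i, :] = -np.inf
        A[:, j] = -np.inf
    return perm, signs


def align_draws(draws):
    """Aligned (U, B, Lambda) draw arrays, matched to ``draws.Lambda_ref``."""
    D = draws.n_draws
    U = np.empty_like(draws.U)
    B = np.empty_like(draws.B)
    Lam = np.empty_like(draws.Lambda)
    ref = draws.Lambda_ref
    for s in range(D):
        perm, signs = _greedy_match(ref, draws.Lambda[s])
        U[s] = draws.U[s][:, perm]
        B[s] = draws.B[s][:, perm] * signs[None, :]
        Lam[s] = draws.Lambda[s][:, perm] * signs[None, :]
    return U, B, Lam


def aligned_loading_mean(draws) -> np.ndarray:
    _, _, Lam = align_draws(draws)
    return Lam.mean(axis=0)


def compute_pips(draws) -> PIPTable:
    """Factor-specific and omnibus PIPs from stored indicator draws."""
    if draws.n_draws == 0:
        raise ParameterError("no stored draws")
    if draws.n_draws < 100:
        warnings.warn(f"only {draws.n_draws} stored draws; PIPs will be noisy", stacklevel=2)
    active_raw = draws.U & draws.I[:, :, None]          # (D, p, m)
    pip_omnibus = active_raw.any(axis=2).mean(axis=0)
    U_al, _, _ = align_draws(draws)
    active_al = U_al & draws.I[:, :, None]
    pip_factor = active_al.mean(axis=0)
    return PIPTable(pip_factor=pip_factor, pip_omnibus=pip_omnibus, n_draws=draws.n_draws)


def bfdr(pips: np.ndarray, z: float) -> float:
    """Bayesian FDR of the selection {j : PIP_j >= z} (nan if empty)."""
    sel = np.asarray(pips) >= z
    if not sel.any():
        return float("nan")
    return float(np.mean(1.0 - np.asarray(pips)[sel]))


def bfdr_select(pips, alpha):
    """Smallest PIP threshold z* with BFDR(z*) <= alpha, maximising discoveries.

    Returns ``(selected_indices, z_star, bfdr_at_threshold)``; an empty
    selection (z*=1, bfdr=nan) if no threshold qualifies.
    """
    pips = np.asarray(pips, dtype=float)
    if np.any((pips < 0) | (pips > 1)):
        raise ParameterError("PIPs must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    order = np.argsort(-pips, kind="stable")
    sorted_p = pips[order]
    cum_bfdr = np.cumsum(1.0 - sorted_p) / np.arange(1, pips.size + 1)
    # candidate thresholds are the distinct PIP values; evaluating at the last
    # occurrence of each value gives the full selected set {PIP >= z}
    ok = np.flatnonzero(cum_bfdr <= alpha)
    if ok.size == 0:
        return np.array([], dtype=int), 1.0, float("nan")
    last = ok[-1]
    # extend to include ties at the threshold value
    z_star = sorted_p[last]
    sel = np.flatnonzero(pips >= z_star)
    return sel, float(z_star), bfdr(pips, z_star)


def select_genes(pips: PIPTable, alpha=0.1, mode="omnibus", gene_ids=None, draws=None) -> SelectionResult:
    """BFDR-controlled gene selection from a :class:`PIPTable`.

    ``mode="omnibus"`` thresholds the omnibus PIPs with a single threshold;
    ``mode="per_factor"`` applies a separate BFDR threshold within each
    factor and selects genes passing in any factor.
    """
    p, m = pips.pip_factor.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [f"gene{j}" for j in range(p)]
    if mode == "omnibus":
        idx, z, fdr = bfdr_select(pips.pip_omnibus, alpha)
        # a selected gene "targets" the factors it is active on in a majority
        # of posterior draws
        targets = {
            gene_ids[j]: [l for l in range(m) if pips.pip_factor[j, l] >= 0.5] for j in idx
        }
    elif mode == "per_factor":
        sel = set()
        zs, fdrs = [], []
        targets = {}
        for l in range(m):
            idx_l, z_l, fdr_l = bfdr_select(pips.pip_factor[:, l], alpha)
            zs.append(z_l)
            if not np.isnan(fdr_l):
                fdrs.append(fdr_l)
            for j in idx_l:
                sel.add(int(j))
                targets.setdefault(gene_ids[j], []).append(l)
        idx = np.array(sorted(sel), dtype=int)
        z = float(min(zs)) if zs else 1.0
        fdr = float(np.mean(fdrs)) if fdrs else float("nan")
    else:
        raise ParameterError("mode must be 'omnibus' or 'per_factor'")
    return SelectionResult(
        selected_genes=[gene_ids[j] for j in idx],
        selected_idx=np.asarray(idx, dtype=int),
        threshold=float(z),
        bfdr_at_threshold=float(fdr) if not np.isnan(fdr) else float("nan"),
        alpha=alpha,
        factor_targets=targets,
        mode=mode,
    )


def report(selection: SelectionResult, draws, out_dir, pips: PIPTable | None = None) -> dict:
    """Write the gene table, per-factor loading tables and a JSON manifest.

    Returns the manifest dict.  Deterministic given the draws.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = draws.meta
    gene_ids = meta.get("gene_ids") or [f"gene{j}" for j in range(draws.I.shape[1])]
    ph_ids = meta.get("phenotype_ids") or [f"ph{k:03d}" for k in range(draws.Lambda.shape[1])]
    if pips is None:
        pips = compute_pips(draws)
    p, m = pips.pip_factor.shape

    tab = pd.DataFrame({"gene": gene_ids, "pip_omnibus": pips.pip_omnibus})
    for l in range(m):
        tab[f"pip_factor{l+1}"] = pips.pip_factor[:, l]
    tab["selected"] = [g in set(selection.selected_genes) for g in gene_ids]
    tab["bfdr_threshold"] = selection.threshold
    gene_path = out / "genes.tsv"
    tab.sort_values("pip_omnibus", ascending=False).to_csv(gene_path, sep="\t", index=False)

    lam = aligned_loading_mean(draws)
    involved = sorted({l for ls in selection.factor_targets.values() for l in ls}) or list(range(m))
    rows = []
    for l in involved:
        order = np.argsort(-np.abs(lam[:, l]), kind="stable")
        for k in order:
            rows.append(
                {"factor": l + 1, "phenotype": ph_ids[k], "loading_mean": lam[k, l]}
            )
    load_path = out / "loadings.tsv"
    pd.DataFrame(rows, columns=["factor", "phenotype", "loading_mean"]).to_csv(
        load_path, sep="\t", index=False
    )

    manifest = {
        "alpha": selection.alpha,
        "mode": selection.mode,
        "threshold": selection.threshold,
        "bfdr_at_threshold": None
        if np.isnan(selection.bfdr_at_threshold)
        else selection.bfdr_at_threshold,
        "n_selected": len(selection.selected_genes),
        "selected_genes": list(selection.selected_genes),
        "factor_targets": {g: [l + 1 for l in ls] for g, ls in selection.factor_targets.items()},
        "n_draws": draws.n_draws,
        "chain": {k: meta.get(k) for k in ("iterations", "burn", "thin", "seed", "m")},
        "files": {"genes": gene_path.name, "loadings": load_path.name},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
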