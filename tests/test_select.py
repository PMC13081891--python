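"""PIP computation, BFDR selection and reporting."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleiofm.exceptions import ParameterError
from pleiofm.model import PosteriorDraws
from pleiofm.select import (
    PIPTable,
    aligned_loading_mean,
    bfdr,
    bfdr_select,
    compute_pips,
    report,
    select_genes,
)


def _draws(I, U, Lambda=None, gene_ids=None, phenotype_ids=None):
    I = np.asarray(I, dtype=bool)
    U = np.asarray(U, dtype=bool)
    D, p, m = U.shape
    if Lambda is None:
        ref = np.eye(3)[:, :m] + 0.01
        Lambda = np.tile(ref, (D, 1, 1))
    Lambda = np.asarray(Lambda, dtype=float)
    q = Lambda.shape[1]
    ref = Lambda[0] if D else np.zeros((q, m))
    return PosteriorDraws(
        I=I,
        U=U,
        B=np.where(I[:, :, None] & U, 0.5, 0.0),
        Lambda=Lambda,
        omega2=np.ones((D, m)),
        r=np.zeros((D, 0)),
        m_trajectory=np.full(D, m),
        Lambda_ref=ref,
        F_mean=np.zeros((5, m)),
        meta={"gene_ids": gene_ids, "phenotype_ids": phenotype_ids,
              "iterations": D, "burn": 0, "thin": 1, "seed": 0, "m": m,
              "types": ["continuous"] * q},
    )


class TestComputePips:
    def test_always_on_gives_pip_one(self):
        D, p, m = 120, 2, 2
        d = _draws(np.ones((D, p)), np.ones((D, p, m)))
        pips = compute_pips(d)
        np.testing.assert_allclose(pips.pip_factor, 1.0)
        np.testing.assert_allclose(pips.pip_omnibus, 1.0)

    def test_union_logic_complementary_halves(self):
        # factor 1 active in first half of draws, factor 2 in the other half
        D, p, m = 200, 1, 2
        U = np.zeros((D, p, m), dtype=bool)
        U[: D // 2, 0, 0] = True
        U[D // 2 :, 0, 1] = True
        d = _draws(np.ones((D, p)), U)
        pips = compute_pips(d)
        np.testing.assert_allclose(pips.pip_factor[0], [0.5, 0.5])
        assert pips.pip_omnibus[0] == 1.0

    def test_matches_recount_oracle(self, rng):
        D, p, m = 500, 4, 3
        I = rng.random((D, p)) < 0.6
        U = rng.random((D, p, m)) < 0.4
        d = _draws(I, U)
        pips = compute_pips(d)
        # independent recount (identity alignment since Lambda is constant)
        active = I[:, :, None] & U
        np.testing.assert_allclose(pips.pip_factor, active.sum(axis=0) / D)
        np.testing.assert_allclose(pips.pip_omnibus, active.any(axis=2).sum(axis=0) / D)

    def test_zero_draws_rejected(self):
        d = _draws(np.ones((0, 1)), np.ones((0, 1, 2)))
        with pytest.raises(ParameterError):
            compute_pips(d)

    def test_alignment_undoes_label_switching(self, rng):
        # permute/flip factor columns in half the draws; aligned factor PIPs
        # must match the unpermuted reference
        D, p, q, m = 300, 3, 6, 2
        ref = np.zeros((q, m))
        ref[:3, 0] = 1.0
        ref[3:, 1] = -1.0
        U = np.zeros((D, p, m), dtype=bool)
        U[:, 0, 0] = True          # gene 0 active only on factor 1
        Lam = np.tile(ref, (D, 1, 1))
        flip = rng.random(D) < 0.5
        U_obs = U.copy()
        Lam_obs = Lam.copy()
        U_obs[flip] = U[flip][:, :, ::-1]
        Lam_obs[flip] = -Lam[flip][:, :, ::-1]
        d = _draws(np.ones((D, p)), U_obs, Lambda=Lam_obs)
        d.Lambda_ref = ref
        pips = compute_pips(d)
        np.testing.assert_allclose(pips.pip_factor[0], [1.0, 0.0])
        lam_mean = aligned_loading_mean(d)
        np.testing.assert_allclose(lam_mean, ref, atol=1e-12)


class TestBfdrSelect:
    def test_worked_example(self):
        # BFDR over {.99,.95} = .03 <= .05; adding .60 gives .153 > .05
        pips = np.array([0.99, 0.95, 0.60, 0.10])
        sel, z, fdr = bfdr_select(pips, alpha=0.05)
        assert sorted(sel) == [0, 1]
        assert z == pytest.approx(0.95)
        assert fdr == pytest.approx(0.03)

    def test_matches_exhaustive_threshold_scan(self, rng):
        for _ in range(50):
            pips = np.round(rng.random(12), 3)
            alpha = float(rng.uniform(0.02, 0.5))
            sel, z, _ = bfdr_select(pips, alpha)
            # brute force: best selection over all distinct thresholds
            best = np.array([], dtype=int)
            for zc in np.unique(pips)[::-1]:
                s = np.flatnonzero(pips >= zc)
                if np.mean(1 - pips[s]) <= alpha and s.size > best.size:
                    best = s
            assert sorted(sel) == sorted(best)

    def test_all_ones_selects_everything(self):
        sel, z, fdr = bfdr_select(np.ones(5), alpha=0.05)
        assert len(sel) == 5
        assert fdr == 0.0

    def test_small_alpha_empty_selection(self):
        sel, z, fdr = bfdr_select(np.array([0.8, 0.7]), alpha=0.01)
        assert len(sel) == 0
        assert np.isnan(fdr)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            bfdr_select(np.array([1.2]), 0.1)
        with pytest.raises(ParameterError):
            bfdr_select(np.array([0.5]), 1.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        pips=st.lists(st.floats(0, 1), min_size=1, max_size=30),
        alpha=st.floats(0.01, 0.5),
    )
    def test_bfdr_monotone_and_nested(self, pips, alpha):
        pips = np.asarray(pips)
        zs = np.unique(pips)
        vals = [bfdr(pips, z) for z in zs]
        vals = [v for v in vals if not np.isnan(v)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        sel_small, _, _ = bfdr_select(pips, max(alpha / 2, 0.005))
        sel_big, _, _ = bfdr_select(pips, alpha)
        assert set(sel_small) <= set(sel_big)


class TestSelectGenes:
    def _pips(self):
        pf = np.array([[0.98, 0.2], [0.1, 0.97], [0.05, 0.02]])
        return PIPTable(pip_factor=pf, pip_omnibus=pf.max(axis=1) + 0.01, n_draws=500)

    def test_omnibus_mode(self):
        sel = select_genes(self._pips(), alpha=0.1, gene_ids=["a", "b", "c"])
        assert sel.selected_genes == ["a", "b"]
        assert sel.factor_targets["a"] == [0]
        assert sel.factor_targets["b"] == [1]

    def test_per_factor_mode(self):
        sel = select_genes(self._pips(), alpha=0.1, mode="per_factor", gene_ids=["a", "b", "c"])
        assert sel.selected_genes == ["a", "b"]

    def test_union_bound_enforced(self):
        with pytest.raises(ParameterError):
            PIPTable(pip_factor=np.array([[0.9]]), pip_omnibus=np.array([0.5]), n_draws=10)


class TestReport:
    def test_empty_selection_writes_header_only(self, tmp_path):
        d = _draws(np.zeros((150, 2)), np.zeros((150, 2, 2)), gene_ids=["a", "b"],
                   phenotype_ids=["p1", "p2", "p3"])
        pips = compute_pips(d)
        sel = select_genes(pips, alpha=0.1, gene_ids=["a", "b"])
        manifest = report(sel, d, tmp_path, pips=pips)
        assert manifest["n_selected"] == 0
        genes = pd.read_csv(tmp_path / "genes.tsv", sep="\t")
        assert len(genes) == 2 and not genes["selected"].any()

    def test_round_trip_and_sorted_loadings(self, tmp_path, rng):
        D, p, q, m = 200, 3, 5, 2
        Lam = np.tile(rng.standard_normal((q, m)), (D, 1, 1))
        d = _draws(np.ones((D, p)), np.ones((D, p, m)), Lambda=Lam,
                   gene_ids=list("abc"), phenotype_ids=[f"p{k}" for k in range(q)])
        pips = compute_pips(d)
        sel = select_genes(pips, alpha=0.1, gene_ids=list("abc"))
        report(sel, d, tmp_path, pips=pips)
        genes = pd.read_csv(tmp_path / "genes.tsv", sep="\t")
        np.testing.assert_allclose(np.sort(genes["pip_omnibus"]), np.sort(pips.pip_omnibus))
        loads = pd.read_csv(tmp_path / "loadings.tsv", sep="\t")
        for _, grp in loads.groupby("factor"):
            mags = grp["loading_mean"].abs().to_numpy()
            assert np.all(np.diff(mags) <= 1e-12)  # descending within factor
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["n_draws"] == D
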