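"""Spike-and-slab expression models, GReX imputation, weight TSV dialect."""

import numpy as np
import pandas as pd
import pytest

from pleiofm.exceptions import DataError, FormatError, InsufficientDataError, MissingSNPError
from pleiofm.expression import (
    GeneWeights,
    SparseExpressionModel,
    fit_region_weights,
    impute_grex,
    read_weights,
    write_weights,
)


def _std(Z):
    return (Z - Z.mean(0)) / Z.std(0)


class TestSparseExpressionModel:
    def test_perfect_signal_recovers_unit_weight(self, rng):
        Z = _std(rng.standard_normal((200, 3)))
        x = Z[:, 0].copy()
        res = SparseExpressionModel(x, Z, standardize=False).fit(
            iterations=1200, burn=600, seed=0
        )
        assert res.gamma_hat[0] == pytest.approx(1.0, abs=0.05)
        assert res.spike_prob[0] < 0.05

    def test_null_gene_shrinks_to_zero(self, rng):
        Z = _std(rng.standard_normal((250, 10)))
        x = rng.standard_normal(250)
        res = SparseExpressionModel(x, Z, standardize=False).fit(
            iterations=2000, burn=1000, seed=1
        )
        assert np.all(np.abs(res.gamma_hat) < 0.1 * x.std())

    def test_matches_enumeration_oracle_on_two_snps(self, rng):
        # posterior spike-pattern probabilities vs exhaustive enumeration with
        # closed-form marginal likelihoods at fixed hyperparameters
        n, g = 60, 2
        Z = _std(rng.standard_normal((n, g)))
        x = 0.35 * Z[:, 0] + 0.9 * rng.standard_normal(n)
        x -= x.mean()
        pi, v2, s2 = 0.5, 1.0, 0.8
        logp = {}
        for pat in [(0, 0), (0, 1), (1, 0), (1, 1)]:  # 1 = spike
            act = [d for d in range(g) if pat[d] == 0]
            C = np.eye(n) * s2
            if act:
                C += v2 * s2 * Z[:, act] @ Z[:, act].T
            _, ld = np.linalg.slogdet(C)
            ll = -0.5 * (n * np.log(2 * np.pi) + ld + x @ np.linalg.solve(C, x))
            logp[pat] = ll + sum(np.log(pi if b else 1 - pi) for b in pat)
        mx = max(logp.values())
        norm = sum(np.exp(v - mx) for v in logp.values())
        res = SparseExpressionModel(x, Z, standardize=False).fit(
            iterations=10_000, burn=2_000, thin=1, seed=3,
            fix_pi=pi, fix_v2=v2, fix_sigma2=s2,
        )
        S = res.spike_draws.astype(int)
        for pat, lp in logp.items():
            oracle = np.exp(lp - mx) / norm
            freq = np.mean(np.all(S == np.array(pat), axis=1))
            assert freq == pytest.approx(oracle, abs=0.04)

    def test_posterior_mean_shrinkage_monotone_in_spike_prior(self, rng):
        # 1-SNP conjugate case: |gamma_hat| non-increasing as the prior spike
        # probability grows (pi fixed, I=1 selects the spike)
        Z = _std(rng.standard_normal((100, 1)))
        x = 0.4 * Z[:, 0] + rng.standard_normal(100)
        x -= x.mean()
        means = []
        for pi in (0.1, 0.5, 0.9):
            res = SparseExpressionModel(x, Z, standardize=False).fit(
                iterations=4000, burn=1000, thin=1, seed=5,
                fix_pi=pi, fix_v2=1.0, fix_sigma2=1.0,
            )
            means.append(abs(res.gamma_hat[0]))
        assert means[0] >= means[1] >= means[2]

    def test_input_validation(self, rng):
        with pytest.raises(InsufficientDataError):
            SparseExpressionModel(np.zeros(2), np.zeros((2, 1)))
        with pytest.raises(DataError):
            SparseExpressionModel(np.array([1.0, np.nan, 0.0]), np.ones((3, 1)))

    def test_degenerate_snp_column_dropped_with_warning(self, rng):
        Z = rng.standard_normal((50, 3))
        Z[:, 1] = 2.0
        x = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="zero-variance"):
            model = SparseExpressionModel(x, Z)
        assert model.Z.shape[1] == 2
        assert model.snp_ids == ["snp0", "snp2"]

    def test_batch_matches_single_gene_shapes(self, rng):
        expr = rng.standard_normal((80, 3))
        Z = [_std(rng.standard_normal((80, 4))) for _ in range(3)]
        ws = fit_region_weights(
            expr, Z, [f"g{j}" for j in range(3)],
            [[f"g{j}s{d}" for d in range(4)] for j in range(3)],
            mcmc=dict(iterations=300, burn=150), seed=0,
        )
        assert len(ws) == 3
        assert all(w.gamma_hat.shape == (4,) for w in ws)


class TestImputeGrex:
    def test_single_snp_identity(self, rng):
        Z = pd.DataFrame(_std(rng.standard_normal((100, 2))), columns=["s1", "s2"])
        w = GeneWeights("g1", ["s1"], np.array([1.0]))
        grex = impute_grex(Z, [w])
        np.testing.assert_allclose(grex.values[:, 0], Z["s1"].to_numpy(), atol=1e-12)

    def test_zero_weight_gene_excluded(self, rng):
        Z = pd.DataFrame(_std(rng.standard_normal((50, 1))), columns=["s1"])
        with pytest.warns(UserWarning, match="all-zero"):
            grex = impute_grex(Z, [GeneWeights("g1", ["s1"], np.array([0.0]))])
        assert grex.gene_ids == []
        assert grex.values.shape == (50, 0)

    def test_matches_matrix_product_oracle(self, rng):
        n, g = 100, 6
        Z = _std(rng.standard_normal((n, g)))
        snps = [f"s{d}" for d in range(g)]
        gamma = rng.standard_normal(g)
        w = GeneWeights("g1", snps, gamma)
        grex = impute_grex(Z, [w], snp_ids=snps)
        raw = Z @ gamma
        np.testing.assert_allclose(
            grex.values[:, 0], (raw - raw.mean()) / raw.std(), atol=1e-10
        )

    def test_missing_snp_raises_keyed_error(self, rng):
        Z = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 1)), columns=["s1"])
        with pytest.raises(MissingSNPError) as exc:
            impute_grex(Z, [GeneWeights("gX", ["sMISSING"], np.array([1.0]))])
        assert exc.value.gene_id == "gX"
        assert exc.value.snp_id == "sMISSING"


class TestWeightsIO:
    def test_round_trip(self, tmp_path, rng):
        ws = [
            GeneWeights("g1", ["a", "b"], np.array([0.5, -0.2]), spike_prob=np.array([0.1, 0.9])),
            GeneWeights("g2", ["c"], np.array([1.5]), spike_prob=np.array([0.0])),
        ]
        path = tmp_path / "w.tsv"
        write_weights(ws, path)
        back = read_weights(path)
        assert [w.gene_id for w in back] == ["g1", "g2"]
        np.testing.assert_allclose(back[0].gamma_hat, ws[0].gamma_hat)
        np.testing.assert_allclose(back[0].spike_prob, ws[0].spike_prob)

    def test_unknown_columns_preserved(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("gene\trsid\tweight\tnote\ng1\ta\t0.5\thello\n")
        back = read_weights(path)
        assert back[0].extra["note"] == ["hello"]
        out = tmp_path / "w2.tsv"
        write_weights(back, out)
        assert "note" in out.read_text().splitlines()[0]

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("gene\trsid\tweight\n")
        assert read_weights(path) == []

    def test_duplicate_gene_snp_row_rejected(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("gene\trsid\tweight\ng1\ta\t0.5\ng1\ta\t0.7\n")
        with pytest.raises(FormatError, match="duplicated"):
            read_weights(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("gene\tsnp\tvalue\ng1\ta\t0.5\n")
        with pytest.raises(FormatError, match="line 1"):
            read_weights(path)
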