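"""Approximate Bayes factors and regional colocalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowgwas import assoc, coloc
from flowgwas.synthdata import Block, SimConfig, simulate_genotypes


class TestAbf:
    def test_zero_prior_variance_collapses_to_zero(self):
        assert coloc.abf(np.array([1.0]), np.array([0.2]), 0.0)[0] == pytest.approx(0.0)

    def test_zero_beta_gives_negative_half_log_ratio(self):
        se, w = 0.1, 0.01
        out = coloc.abf(np.array([0.0]), np.array([se]), w)[0]
        assert out == pytest.approx(0.5 * np.log(se**2 / (se**2 + w)))
        assert out < 0

    @given(
        st.floats(-2, 2), st.floats(0.01, 1.0), st.floats(0.0, 0.5)
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_direct_formula(self, beta, se, w):
        # independent evaluation of the closed form
        z = beta / se
        expected = np.log(np.sqrt(se**2 / (se**2 + w))) + z**2 / 2 * (w / (se**2 + w))
        assert coloc.abf(np.array([beta]), np.array([se]), w)[0] == pytest.approx(
            expected, abs=1e-12
        )

    def test_non_positive_se_rejected(self):
        with pytest.raises(ValueError):
            coloc.abf(np.array([1.0]), np.array([0.0]), 0.1)


def _stats(ids, beta, se):
    return pd.DataFrame({"id": ids, "beta": beta, "se": se})


class TestPairwisePP:
    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(0)
        ids = [f"v{j}" for j in range(20)]
        s1 = _stats(ids, rng.normal(0, 0.05, 20), np.full(20, 0.02))
        s2 = _stats(ids, rng.normal(0, 0.05, 20), np.full(20, 0.02))
        res = coloc.pairwise_pp(s1, s2)
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-12)

    def test_null_region_dominated_by_h0(self):
        ids = [f"v{j}" for j in range(30)]
        s = _stats(ids, np.zeros(30), np.full(30, 0.02))
        res = coloc.pairwise_pp(s, s)
        assert res.pp["H0"] > 0.99
        assert not res.passes

    def test_shared_causal_variant_detected(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(n_samples=2000, seed=2, blocks=[Block("1", 40, (0.2, 0.5), 0.6)])
        g = simulate_genotypes(cfg)
        x = g.dosages[:, 20]
        y1 = 0.4 * x + rng.normal(0, 1, 2000)
        y2 = 0.3 * x + rng.normal(0, 1, 2000)
        s1 = assoc.run_univariable((y1 - y1.mean()) / y1.std(), g)
        s2 = assoc.run_univariable((y2 - y2.mean()) / y2.std(), g)
        res = coloc.pairwise_pp(s1[["id", "beta", "se"]], s2[["id", "beta", "se"]])
        assert res.shared_pp > 0.8 and res.passes

    def test_distinct_causal_variants_rejected(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(
            n_samples=2000,
            seed=4,
            blocks=[Block("1", 20, (0.2, 0.5), 0.0), Block("1", 20, (0.2, 0.5), 0.0)],
        )
        g = simulate_genotypes(cfg)
        y1 = 0.4 * g.dosages[:, 5] + rng.normal(0, 1, 2000)
        y2 = 0.4 * g.dosages[:, 30] + rng.normal(0, 1, 2000)
        s1 = assoc.run_univariable((y1 - y1.mean()) / y1.std(), g)
        s2 = assoc.run_univariable((y2 - y2.mean()) / y2.std(), g)
        res = coloc.pairwise_pp(s1[["id", "beta", "se"]], s2[["id", "beta", "se"]])
        assert res.shared_pp < 0.2
        assert res.pp["H3"] > res.pp["H4"]

    def test_shared_pp_monotone_in_shared_prior(self):
        rng = np.random.default_rng(5)
        ids = [f"v{j}" for j in range(15)]
        b = rng.normal(0, 0.1, 15)
        s1 = _stats(ids, b + rng.normal(0, 0.01, 15), np.full(15, 0.02))
        s2 = _stats(ids, b + rng.normal(0, 0.01, 15), np.full(15, 0.02))
        pps = [
            coloc.pairwise_pp(s1, s2, coloc.ColocPriors(p12=p12)).shared_pp
            for p12 in (1e-6, 1e-5, 1e-4)
        ]
        assert pps[0] < pps[1] < pps[2]

    def test_empty_intersection_raises(self):
        s1 = _stats(["a", "b"], [0.1, 0.1], [0.02, 0.02])
        s2 = _stats(["c", "d"], [0.1, 0.1], [0.02, 0.02])
        with pytest.raises(ValueError):
            coloc.pairwise_pp(s1, s2)


class TestResidualizeSecondary:
    def test_single_conditional_variant_identity(self):
        cfg = SimConfig(n_samples=1000, seed=6, blocks=[Block("1", 10, (0.2, 0.5), 0.5)])
        g = simulate_genotypes(cfg)
        rng = np.random.default_rng(7)
        y = 0.3 * g.dosages[:, 4] + rng.normal(0, 1, 1000)
        target = g.variants["id"][4]
        adj = coloc.residualize_secondary(y, g, [target], target)
        raw = assoc.run_univariable(y, g)
        assert np.allclose(adj["beta"], raw["beta"], atol=1e-9)

    def test_secondary_signal_removed(self):
        removed = 0
        for seed in range(20):
            cfg = SimConfig(
                n_samples=2000,
                seed=seed,
                blocks=[Block("1", 10, (0.3, 0.5), 0.0), Block("1", 10, (0.3, 0.5), 0.0)],
            )
            g = simulate_genotypes(cfg)
            rng = np.random.default_rng(seed + 100)
            y = 0.3 * g.dosages[:, 2] + 0.3 * g.dosages[:, 15] + rng.normal(0, 1, 2000)
            ids = g.variants["id"]
            adj = coloc.residualize_secondary(y, g, [ids[2], ids[15]], ids[2])
            removed += adj.loc[adj["id"] == ids[15], "p"].iloc[0] > 0.05
        assert removed >= 19

    def test_orthogonal_secondary_leaves_betas(self):
        cfg = SimConfig(
            n_samples=3000,
            seed=8,
            blocks=[Block("1", 5, (0.3, 0.5), 0.5)],
        )
        g = simulate_genotypes(cfg)
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 3000)
        ids = g.variants["id"].tolist()
        # make a synthetic secondary variant exactly orthogonal to the region
        region = np.column_stack([np.ones(3000)] + [g.column(v) for v in ids])
        q, _ = np.linalg.qr(region)
        sec = rng.normal(size=3000)
        sec = sec - q @ (q.T @ sec)
        g2 = type(g)(
            dosages=np.column_stack([g.dosages, sec]),
            variants=pd.concat(
                [g.variants, pd.DataFrame([{"id": "sec", "chrom": "1", "pos": 9, "ref": "A",
                                            "alt": "G", "maf": 0.4, "info": 1.0, "block": 9}])],
                ignore_index=True,
            ),
            samples=g.samples,
        )
        adj = coloc.residualize_secondary(y, g2, ["sec", ids[0]], ids[0])
        raw = assoc.run_univariable(y, g2)
        keep = adj["id"].isin(ids)
        assert np.allclose(adj.loc[keep, "beta"], raw.loc[keep, "beta"], atol=1e-6)

    def test_all_in_ld_logs_identity(self):
        cfg = SimConfig(n_samples=500, seed=10, blocks=[Block("1", 4, (0.3, 0.5), 0.5)])
        g = simulate_genotypes(cfg)
        y = np.random.default_rng(11).normal(size=500)
        dup = type(g)(
            dosages=np.column_stack([g.dosages, g.dosages[:, 0]]),
            variants=pd.concat(
                [g.variants, g.variants.iloc[[0]].assign(id="dup")], ignore_index=True
            ),
            samples=g.samples,
        )
        adj = coloc.residualize_secondary(y, dup, [g.variants["id"][0], "dup"], "dup")
        raw = assoc.run_univariable(y, dup)
        assert np.allclose(adj["beta"], raw["beta"], atol=1e-12)
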