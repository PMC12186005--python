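import itertools

import numpy as np
import pandas as pd
import pytest

from seascapegen.pipeline import _merge_lfmm
from seascapegen.selection_scan import (
    ScanResult,
    bh_fdr,
    consensus_outliers,
    fsthet_scan,
    gea_lfmm_lite,
    pca_outlier_scan,
    rda_scan,
)
from seascapegen.synthetic_data import SimulationParams, simulate_dataset

from ._oracles import bh_stepup_oracle
from .conftest import make_env, make_gm


class TestBhFdr:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_vectors(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_on_grid(self):
        """All p-vectors of length <= 6 over a fixed grid match step-up."""
        grid = [0.001, 0.04, 0.2, 0.6, 1.0]
        for k in range(1, 5):
            for combo in itertools.product(grid, repeat=k):
                np.testing.assert_allclose(
                    bh_fdr(combo), bh_stepup_oracle(combo), atol=1e-12
                )
        # longer vectors: sampled combinations
        rng = np.random.default_rng(0)
        for _ in range(300):
            combo = rng.choice(grid, size=rng.integers(5, 7))
            np.testing.assert_allclose(
                bh_fdr(combo), bh_stepup_oracle(combo), atol=1e-12
            )

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFsthet:
    def test_interior_locus_is_neutral(self, neutral_dataset):
        sr = fsthet_scan(neutral_dataset.gm)
        t = sr.table.dropna(subset=["stat"])
        median_locus = (t.stat - t.stat.median()).abs().idxmin()
        assert t.loc[median_locus, "flag"] == "neutral"

    def test_null_flag_rate_near_nominal(self, neutral_dataset):
        sr = fsthet_scan(neutral_dataset.gm)
        rate = (sr.table.flag != "neutral").mean()
        se = np.sqrt(0.05 * 0.95 / len(sr.table))
        assert abs(rate - 0.05) < 3 * se

    def test_planted_clines_flagged_divergent(self):
        """Strong clines at 1% contamination: most planted loci flagged.

        Quantile-envelope scans can never flag more of a heterozygosity bin
        than the nominal tail, so the recall calibration keeps the planted
        fraction below that tail.
        """
        ds = simulate_dataset(
            SimulationParams(
                n_neutral_loci=1980, n_adaptive_loci=20, n_paralog_loci=0,
                beta_env=1.5, adaptive_variables=("temperature",), seed=42,
            )
        )
        sr = fsthet_scan(ds.gm)
        adaptive = ds.truth.index[ds.truth["class"] == "adaptive"]
        frac = (sr.table.loc[adaptive, "flag"] == "divergent").mean()
        assert frac >= 0.5


class TestPcaOutlier:
    def test_fixed_difference_locus_has_largest_distance(self):
        # moderately differentiated background puts the group split on PC1;
        # the single fixed-difference locus must then top the distance ranking
        rng = np.random.default_rng(0)
        p_a = rng.uniform(0.35, 0.65, 100)
        p_b = np.clip(p_a + rng.choice([-1, 1], 100) * 0.15, 0.05, 0.95)
        calls = np.vstack(
            [rng.binomial(2, p_a, size=(30, 100)), rng.binomial(2, p_b, size=(30, 100))]
        ).astype(np.int8)
        calls[:, 0] = [2] * 30 + [0] * 30  # group-fixed difference
        popmap = {f"s{i}": ("X" if i < 30 else "Y") for i in range(60)}
        gm = make_gm(calls, popmap)
        sr = pca_outlier_scan(gm, k=1)
        assert sr.table["stat"].idxmax() == gm.locus_ids[0]

    def test_null_pvalues_roughly_uniform(self, neutral_dataset):
        from scipy.stats import kstest

        sr = pca_outlier_scan(neutral_dataset.gm, k=2)
        stat, _ = kstest(sr.table.p, "uniform")
        assert stat < 0.08

    def test_panmictic_inflation_near_one(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.4, size=(100, 400)).astype(np.int8)
        gm = make_gm(calls, {f"s{i}": "X" for i in range(100)})
        sr = pca_outlier_scan(gm, k=1)
        assert sr.table.attrs["gif"] == pytest.approx(1.0, abs=0.25)

    def test_k_out_of_range(self, neutral_dataset):
        with pytest.raises(ValueError, match="K="):
            pca_outlier_scan(neutral_dataset.gm, k=10_000)


class TestLfmm:
    def test_constant_environment_rejected(self, neutral_dataset):
        env = neutral_dataset.env
        df = env.df.copy()
        for s in ("mean", "min", "max", "range"):
            df[f"salinity_{s}"] = 30.0 if s != "range" else 0.0
        from seascapegen.io_core import EnvTable

        env2 = EnvTable(df)
        with pytest.raises(ValueError, match="constant"):
            gea_lfmm_lite(neutral_dataset.gm, env2, "salinity", k=2)

    def test_planted_cline_power(self, small_dataset):
        ds = small_dataset
        sr = gea_lfmm_lite(ds.gm, ds.env, "temperature", k=2)
        truth = ds.truth
        planted = truth.index[
            (truth["class"] == "adaptive") & (truth["variable"] == "temperature")
        ]
        power = (sr.table.loc[planted, "flag"] == "divergent").mean()
        assert power >= 0.8

    def test_null_type_one_error(self, neutral_dataset):
        sr = gea_lfmm_lite(neutral_dataset.gm, neutral_dataset.env, "nitrate", k=2)
        rate = (sr.table.p < 0.05).mean()
        assert abs(rate - 0.05) < 0.03


class TestRda:
    def test_null_flags_below_tail_bound(self, neutral_dataset):
        sr = rda_scan(neutral_dataset.gm, neutral_dataset.env, seed=0)
        assert (sr.table.flag == "divergent").mean() <= 0.01

    def test_single_strong_cline_assigns_right_variable(self):
        """With temperature decorrelated from the other variables, flagged
        planted loci are attributed to temperature."""
        import pandas as pd
        from scipy.special import expit

        from seascapegen.io_core import EnvTable

        n_demes, n_neutral, n_adaptive = 10, 300, 30
        rng = np.random.default_rng(8)
        temp = np.arange(n_demes, dtype=float)  # monotone gradient
        sal = np.array([3.0, 0, 7, 1, 9, 2, 8, 0, 6, 4])  # jumbled profile
        data = {"latitude": temp, "longitude": temp}
        for name, prof in (("temperature", temp), ("salinity", sal)):
            data[f"{name}_mean"] = prof
            data[f"{name}_min"] = prof - 1
            data[f"{name}_max"] = prof + 1
        env = EnvTable(
            pd.DataFrame(data, index=pd.Index([f"L{i}" for i in range(n_demes)], name="location"))
        )
        z = (temp - temp.mean()) / temp.std()
        p_neutral = rng.uniform(0.2, 0.8, n_neutral)
        freqs_neutral = np.clip(
            rng.normal(p_neutral, 0.03, size=(n_demes, n_neutral)), 0.01, 0.99
        )
        signs = rng.choice([-1, 1], n_adaptive)
        freqs_adaptive = expit(2.0 * signs[None, :] * z[:, None])
        freqs = np.hstack([freqs_neutral, freqs_adaptive])
        calls = np.vstack(
            [rng.binomial(2, freqs[d], size=(20, freqs.shape[1])) for d in range(n_demes)]
        ).astype(np.int8)
        popmap = {f"s{i}": f"L{i // 20}" for i in range(200)}
        gm = make_gm(calls, popmap)
        sr = rda_scan(gm, env, seed=0)
        adaptive_ids = set(gm.locus_ids[n_neutral:])
        flagged_true = sr.table[
            (sr.table.flag == "divergent") & sr.table.index.isin(adaptive_ids)
        ]
        assert len(flagged_true) > 0
        assert (flagged_true["variable"] == "temperature").mean() >= 0.9

    def test_mean_loading_never_flagged(self, neutral_dataset):
        # a locus sitting exactly at the loading mean has zdev 0 < any bound
        sr = rda_scan(neutral_dataset.gm, neutral_dataset.env, loading_sd=0.0 + 1e-9, seed=0)
        center = sr.table["stat"].idxmin()
        # even with a near-zero threshold the minimal-deviation locus survives
        assert sr.table.loc[center, "stat"] >= 0

    def test_collinear_variable_dropped(self, neutral_dataset):
        from seascapegen.io_core import EnvTable

        df = neutral_dataset.env.df.copy()
        for s in ("mean", "min", "max", "range"):
            df[f"silicate_{s}"] = df[f"temperature_{s}"] * 2 + (0 if s == "range" else 1)
        env2 = EnvTable(df)
        with pytest.warns(UserWarning, match="collinear"):
            rda_scan(neutral_dataset.gm, env2, seed=0, n_perm=9)


class TestConsensus:
    def _mk(self, method, flags):
        idx = [f"l{i}" for i in range(len(flags))]
        return ScanResult(
            method=method,
            table=pd.DataFrame({"flag": flags}, index=idx),
        )

    def test_single_method_flag_not_enough(self):
        a = self._mk("fsthet", ["divergent", "neutral"])
        b = self._mk("lfmm", ["neutral", "neutral"])
        cons = consensus_outliers([a, b], min_methods=2)
        assert cons.pgd_set == set() and cons.adaptive_set == set()

    def test_cross_approach_pair_counts_and_shares(self):
        a = self._mk("fsthet", ["divergent", "neutral"])
        b = self._mk("lfmm", ["divergent", "neutral"])
        cons = consensus_outliers([a, b], min_methods=2)
        assert cons.adaptive_set == {"l0"}
        assert cons.shared_set == {"l0"}
        assert "l1" in cons.neutral_set

    def test_within_mode_requires_same_class(self):
        a = self._mk("fsthet", ["divergent"])
        b = self._mk("lfmm", ["divergent"])
        cons = consensus_outliers([a, b], min_methods=2, mode="within")
        assert cons.pgd_set == set() and cons.gea_set == set()

    def test_balancing_excluded_from_both_sets(self):
        a = self._mk("fsthet", ["balancing", "divergent"])
        b = self._mk("lfmm", ["neutral", "divergent"])
        cons = consensus_outliers([a, b])
        assert "l0" not in cons.adaptive_set and "l0" not in cons.neutral_set
        assert "l0" in cons.balancing_set

    def test_mismatched_universe_rejected(self):
        a = self._mk("fsthet", ["neutral"])
        b = ScanResult("lfmm", pd.DataFrame({"flag": ["neutral"]}, index=["other"]))
        with pytest.raises(ValueError, match="different locus sets"):
            consensus_outliers([a, b])

    def test_shared_subset_invariant_on_simulation(self, small_dataset):
        ds = small_dataset
        scans = [
            fsthet_scan(ds.gm),
            pca_outlier_scan(ds.gm, k=2),
            rda_scan(ds.gm, ds.env, seed=1),
        ]
        lf = [gea_lfmm_lite(ds.gm, ds.env, v, k=2) for v in ds.env.variables]
        scans.append(_merge_lfmm([s.table for s in lf]))
        cons = consensus_outliers(scans)
        assert cons.shared_set <= cons.pgd_set
        assert cons.shared_set <= cons.gea_set
        universe = set(scans[0].table.index)
        assert cons.adaptive_set | cons.neutral_set | cons.balancing_set <= universe
        assert cons.adaptive_set.isdisjoint(cons.neutral_set)

    def test_locus_order_invariance(self, small_dataset):
        ds = small_dataset
        gm2 = ds.gm.subset(locus_idx=np.random.default_rng(0).permutation(ds.gm.n_loci))
        s1 = pca_outlier_scan(ds.gm, k=2).divergent
        s2 = pca_outlier_scan(gm2, k=2).divergent
        assert s1 == s2
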