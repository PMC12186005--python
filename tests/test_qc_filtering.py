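import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seascapegen.io_core import MISSING, DepthTable
from seascapegen.qc_filtering import (
    FilterConfig,
    filter_call_rate,
    filter_hwe,
    filter_maf,
    filter_paralogs,
    hdplot_stats,
    hwe_exact_test,
    maf_per_location,
    run_filter_cascade,
    select_one_snp_per_tag,
)
from seascapegen.synthetic_data import SimulationParams, simulate_dataset

from ._oracles import hwe_exact_oracle, wc_abc_oracle
from .conftest import make_gm


class TestMaf:
    def test_direct_counts(self):
        gm = make_gm([[0], [0], [1]], {"a": "X", "b": "X", "c": "X"})
        maf = maf_per_location(gm)
        assert maf.iloc[0, 0] == pytest.approx(1 / 6)

    def test_monomorphic_is_zero_and_all_missing_is_nan(self):
        gm = make_gm(
            [[2, MISSING], [2, MISSING]], {"a": "X", "b": "X"}
        )
        maf = maf_per_location(gm)
        assert maf.iloc[0, 0] == 0.0
        assert np.isnan(maf.iloc[1, 0])

    def test_retention_rule_any_vs_all(self):
        # locus 0: MAF 0.04 everywhere; locus 1: common in X only
        calls = np.zeros((20, 2), dtype=np.int8)
        calls[0, 0] = 1  # X: f=1/20 -> 0.05? use 10 per pop: f = 1/20 = 0.05
        calls[0, 0] = 0
        # construct explicitly: pop X samples 0-9, pop Y samples 10-19
        calls[:, 0] = 0
        calls[0, 0] = 1  # X MAF = 1/20 = 0.05 -> below 0.06
        calls[:5, 1] = 2  # X MAF: f = 10/20 -> 0.5; Y monomorphic
        popmap = {f"s{i}": ("X" if i < 10 else "Y") for i in range(20)}
        gm = make_gm(calls, popmap)
        kept_any = filter_maf(gm, 0.06, rule="any")
        assert list(kept_any.locus_ids) == ["t1_11"]
        kept_all = filter_maf(gm, 0.06, rule="all")
        assert kept_all.n_loci == 0

    def test_invalid_threshold(self):
        gm = make_gm([[0]], {"a": "X"})
        with pytest.raises(ValueError):
            filter_maf(gm, 0.0)


class TestCallRate:
    def test_locus_then_sample_enumeration(self):
        """5x5 matrix with a hand-enumerated missing pattern."""
        M = MISSING
        calls = np.array(
            [
                [0, M, 1, M, 2],
                [1, M, 0, M, 2],
                [2, M, 1, 0, 1],
                [M, M, M, M, M],
                [0, 1, 2, 0, 1],
            ],
            dtype=np.int8,
        )
        gm = make_gm(calls, {f"s{i}": "X" for i in range(5)})
        out, _ = filter_call_rate(gm, locus_min=0.5, sample_min=0.8)
        # locus call rates: .8, .2, .8, .4, .8 -> loci 0,2,4 kept
        # then sample rates over 3 loci: s0..s4 = 1,1,1,0,1 -> s3 dropped
        assert list(out.locus_ids) == ["t0_10", "t2_12", "t4_14"]
        assert out.samples == ["s0", "s1", "s2", "s4"]

    def test_boundary_sample_dropped(self):
        calls = np.zeros((2, 10), dtype=np.int8)
        calls[1, 0] = MISSING  # sample 1 at 90% exactly retained; use 8/10
        calls[1, 1] = MISSING  # 80% < 90%
        gm = make_gm(calls, {"a": "X", "b": "X"})
        out, _ = filter_call_rate(gm, locus_min=0.1, sample_min=0.9)
        assert out.samples == ["a"]


class TestHDplot:
    def test_definition_examples(self):
        # 3 loci: all-het, balanced reads, skewed reads
        calls = np.full((20, 3), 1, dtype=np.int8)
        ref = np.zeros((20, 3), dtype=int)
        alt = np.zeros((20, 3), dtype=int)
        ref[:, 0] = 3; alt[:, 0] = 3
        ref[:, 1] = 5; alt[:, 1] = 5   # x = 100 of n = 200 -> D = 0
        ref[:, 2] = 4; alt[:, 2] = 1   # x = 80 of n = 100 -> D = 6
        gm = make_gm(calls, {f"s{i}": "X" for i in range(20)})
        stats = hdplot_stats(gm, DepthTable(ref=ref, alt=alt))
        assert stats.h[0] == 1.0
        assert stats.d[1] == pytest.approx(0.0)
        assert stats.d[2] == pytest.approx((80 - 50) / np.sqrt(25))

    def test_sign_flip_and_h_invariance_under_allele_relabel(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(30, 4)).astype(np.int8)
        ref = rng.integers(1, 30, size=(30, 4))
        alt = rng.integers(1, 30, size=(30, 4))
        gm = make_gm(calls, {f"s{i}": "X" for i in range(30)})
        s1 = hdplot_stats(gm, DepthTable(ref=ref, alt=alt))
        flipped = make_gm(2 - calls, {f"s{i}": "X" for i in range(30)})
        s2 = hdplot_stats(flipped, DepthTable(ref=alt, alt=ref))
        np.testing.assert_allclose(s1.h, s2.h)
        np.testing.assert_allclose(s1.d, -s2.d)

    def test_negative_depth_rejected(self):
        gm = make_gm([[1]], {"a": "X"})
        dep = DepthTable.__new__(DepthTable)
        dep.ref = np.array([[-1]])
        dep.alt = np.array([[1]])
        with pytest.raises(ValueError, match="negative"):
            hdplot_stats(gm, dep)

    def test_flag_bounds(self):
        gm = make_gm([[1], [1]], {"a": "X", "b": "X"})
        stats = hdplot_stats(gm, DepthTable(ref=[[3], [3]], alt=[[3], [3]]))
        kept, removed = filter_paralogs(gm, stats, h_max=0.6, d_max=5)
        assert kept.n_loci == 0  # H = 1 -> removed
        stats.h[:] = 0.3
        kept, removed = filter_paralogs(gm, stats)
        assert kept.n_loci == 1 and len(removed) == 0


class TestHweExactTest:
    def test_spec_examples(self):
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)
        assert hwe_exact_test(5, 0, 0) == 1.0  # monomorphic

    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exact_rational_enumeration(self, naa, nab, nbb):
        if naa + nab + nbb == 0:
            return
        expected = float(hwe_exact_oracle(naa, nab, nbb))
        assert hwe_exact_test(naa, nab, nbb) == pytest.approx(expected, abs=1e-9)

    def test_filter_hwe_location_threshold(self):
        # locus 0 violates HWE (all hets) in 3 locations; locus 1 in 2
        n = 12
        calls = np.zeros((n * 4, 2), dtype=np.int8)
        popmap = {}
        for loc_i in range(4):
            for k in range(n):
                popmap[f"s{loc_i}_{k}"] = f"L{loc_i}"
        gm_calls = calls.copy()
        gm_calls[: 3 * n, 0] = 1  # all-het in L0..L2
        gm_calls[: 2 * n, 1] = 1  # all-het in L0..L1
        gm = make_gm(gm_calls, popmap)
        out = filter_hwe(gm, alpha=0.05, min_deviating_locations=3)
        assert list(out.locus_ids) == ["t1_11"]

    def test_monomorphic_locus_retained(self):
        gm = make_gm(np.full((30, 1), 2, np.int8), {f"s{i}": f"L{i%3}" for i in range(30)})
        assert filter_hwe(gm).n_loci == 1


class TestOneSnpPerTag:
    def test_highest_fst_snp_kept_against_oracle(self):
        # two SNPs on one tag: SNP 1 strongly differentiated, SNP 0 not
        popmap = {f"s{i}": ("X" if i < 10 else "Y") for i in range(20)}
        rng = np.random.default_rng(1)
        weak = rng.integers(0, 3, size=20).astype(np.int8)
        strong = np.array([2] * 10 + [0] * 10, dtype=np.int8)
        calls = np.column_stack([weak, strong])
        gm = make_gm(calls, popmap, tags=["t1", "t1"], positions=[5, 50])
        # confirm ordering with the independent variance-component oracle
        def theta(col):
            a, b, c = wc_abc_oracle([list(col[:10]), list(col[10:])])
            return a / (a + b + c)
        assert theta(strong) > theta(weak)
        out = select_one_snp_per_tag(gm)
        assert list(out.locus_ids) == ["t1_50"]

    def test_tie_breaks_to_smallest_position(self):
        popmap = {f"s{i}": ("X" if i < 5 else "Y") for i in range(10)}
        col = np.array([0, 1, 2, 1, 0, 2, 1, 0, 1, 2], dtype=np.int8)
        calls = np.column_stack([col, col])  # identical -> identical FST
        gm = make_gm(calls, popmap, tags=["t1", "t1"], positions=[40, 8])
        out = select_one_snp_per_tag(gm)
        assert list(out.locus_ids) == ["t1_8"]

    def test_single_snp_tag_identity(self):
        gm = make_gm([[0], [1], [2], [1]], {"a": "X", "b": "X", "c": "Y", "d": "Y"})
        assert list(select_one_snp_per_tag(gm).locus_ids) == list(gm.locus_ids)


class TestCascade:
    def test_monotone_counts_and_planted_removals(self):
        ds = simulate_dataset(
            SimulationParams(n_neutral_loci=200, n_adaptive_loci=0, n_paralog_loci=20, seed=3)
        )
        gm, report = run_filter_cascade(ds.gm, ds.depths)
        df = report.to_frame()
        assert (df["samples"].diff().dropna() <= 0).all()
        assert (df["loci"].diff().dropna() <= 0).all()
        # HDplot row removes most planted paralogs
        hd = df[df["step"].str.startswith("HDplot")].iloc[0]
        before = df.iloc[df.index[df["step"].str.startswith("HDplot")][0] - 1]
        assert before["loci"] - hd["loci"] >= 0.8 * 20

    def test_skip_hdplot_without_depths(self, small_dataset):
        gm, report = run_filter_cascade(small_dataset.gm, None)
        steps = report.to_frame()["step"].tolist()
        assert any("skipped" in s for s in steps)

    def test_empty_input_no_crash(self):
        gm = make_gm(np.zeros((1, 0), np.int8), {"a": "X"}, tags=[], positions=[])
        out, report = run_filter_cascade(gm, None)
        assert out.n_loci == 0
        assert report.steps[0] == ("input", 1, 0)
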