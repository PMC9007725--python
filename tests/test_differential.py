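import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capmeth.differential import (
    DMRConfig,
    bonferroni_adjust,
    call_dmrs,
    classify_magnitude,
    group_mean_beta,
    log2_fold_enrichment,
    region_t_test,
)

from .conftest import make_samplesheet


def beta_frame(rows: dict, samples):
    return pd.DataFrame(rows, index=samples).T.rename_axis("region_id")


class TestGroupMean:
    def test_simple_mean_and_identity(self):
        sheet = make_samplesheet(2, 1)
        betas = pd.DataFrame({"A0": [0.2], "A1": [0.4], "B0": [0.9]},
                             index=pd.Index(["r1"], name="region_id"))
        assert group_mean_beta(betas, sheet, "NFPA")["r1"] == pytest.approx(0.3)
        assert group_mean_beta(betas, sheet, "GH")["r1"] == pytest.approx(0.9)

    def test_matches_direct_sum(self, rng):
        sheet = make_samplesheet(10, 0)
        betas = pd.DataFrame(
            rng.random((5, 10)), columns=sheet.index,
            index=pd.Index([f"r{i}" for i in range(5)], name="region_id"),
        )
        got = group_mean_beta(betas, sheet, "NFPA")
        for rid in betas.index:
            assert got[rid] == pytest.approx(sum(betas.loc[rid]) / 10)

    def test_absent_group_rejected(self):
        sheet = make_samplesheet(2, 2)
        betas = pd.DataFrame(np.zeros((1, 4)), columns=sheet.index)
        with pytest.raises(ValueError):
            group_mean_beta(betas, sheet, "NORMAL")


class TestLog2FoldEnrichment:
    def test_fourfold_is_two(self):
        assert log2_fold_enrichment(0.8, 0.2, epsilon=1e-12) == pytest.approx(2.0)

    def test_equal_means_zero(self):
        assert log2_fold_enrichment(0.37, 0.37) == pytest.approx(0.0)

    def test_zero_mean_guarded_by_epsilon(self):
        # log2(1e-6 / 0.500001) = -18.93...
        assert log2_fold_enrichment(0.0, 0.5, epsilon=1e-6) == pytest.approx(
            np.log2(1e-6 / 0.500001)
        )
        assert log2_fold_enrichment(0.0, 0.5) == pytest.approx(-18.93, abs=0.01)


class TestRegionTTest:
    def test_identical_groups(self):
        t, p = region_t_test(np.array([0.2, 0.3, 0.4]), np.array([0.4, 0.3, 0.2]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_cohort_age_pvalue_rounds_to_036(self):
        gh = np.array([22, 27, 28, 35, 46, 48, 57, 57, 63, 76], dtype=float)
        nfpa = np.array([36, 40, 42, 46, 46, 55, 68, 70, 72], dtype=float)
        _, p = region_t_test(gh, nfpa, variant="welch")
        assert round(p, 2) == 0.36

    def test_welch_matches_hand_formula(self):
        a = np.array([0.1, 0.2, 0.6])
        b = np.array([0.5, 0.7, 0.9])
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / 3 + vb / 3)
        t_hand = (ma - mb) / se
        df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df)
        t, p = region_t_test(a, b, variant="welch")
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_degenerate_equal_constants(self):
        t, p = region_t_test(np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_distinct_constants_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = region_t_test(np.array([0.2, 0.2]), np.array([0.8, 0.8]))
        assert p == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            region_t_test(np.array([0.1]), np.array([0.2, 0.3]))


class TestBonferroni:
    def test_multiplies_by_m(self):
        assert bonferroni_adjust(np.array([0.001] + [0.5] * 9))[0] == pytest.approx(0.01)

    def test_clamped_at_one(self):
        p = np.full(184841, 0.01)
        assert bonferroni_adjust(p).max() == 1.0

    def test_zero_stays_zero(self):
        assert bonferroni_adjust(np.array([0.0, 0.3]))[0] == 0.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_monotone_and_dominates_raw(self, ps):
        p = np.array(ps)
        adj = bonferroni_adjust(p)
        assert (adj >= p).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


def simulated_betas(rng, n_regions=60, n_a=5, n_b=5, shift=0.0):
    sheet = make_samplesheet(n_a, n_b)
    base = rng.uniform(0.2, 0.8, n_regions)
    a = np.clip(base[:, None] + shift + rng.normal(0, 0.05, (n_regions, n_a)), 0, 1)
    b = np.clip(base[:, None] + rng.normal(0, 0.05, (n_regions, n_b)), 0, 1)
    betas = pd.DataFrame(
        np.hstack([a, b]), columns=sheet.index,
        index=pd.Index([f"r{i}" for i in range(n_regions)], name="region_id"),
    )
    return betas, sheet


class TestCallDmrs:
    def test_threshold_logic(self):
        # two regions: one passes both gates, one fails the LFC gate
        sheet = make_samplesheet(4, 4)
        strong = np.array([0.78, 0.80, 0.82, 0.80, 0.20, 0.21, 0.19, 0.20])
        weak = np.array([0.50, 0.51, 0.49, 0.50, 0.44, 0.45, 0.43, 0.44])
        betas = pd.DataFrame([strong, weak], columns=sheet.index,
                             index=pd.Index(["strong", "weak"], name="region_id"))
        out = call_dmrs(betas, sheet)
        assert bool(out.loc["strong", "significant"])
        assert out.loc["strong", "direction"] == "NFPA_HYPER"
        assert out.loc["weak", "p_adj"] <= 0.05  # significant t, but...
        assert abs(out.loc["weak", "lfc"]) < 0.5
        assert not out.loc["weak", "significant"]  # fails the LFC gate

    def test_label_swap_antisymmetry(self, rng):
        betas, sheet = simulated_betas(rng, shift=0.2)
        swapped = sheet.map({"NFPA": "GH", "GH": "NFPA"})
        a = call_dmrs(betas, sheet).sort_index()
        b = call_dmrs(betas, swapped).sort_index()
        assert np.allclose(a["lfc"], -b["lfc"], atol=1e-9)
        assert np.allclose(a["t_stat"], -b["t_stat"])
        assert np.allclose(a["p_raw"], b["p_raw"])
        assert (a["significant"] == b["significant"]).all()

    def test_sample_order_invariance(self, rng):
        betas, sheet = simulated_betas(rng, shift=0.1)
        perm = rng.permutation(sheet.index)
        a = call_dmrs(betas, sheet).sort_index()
        b = call_dmrs(betas[perm], sheet.loc[perm]).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_h_l_partition_significant(self, rng):
        betas, sheet = simulated_betas(rng, n_regions=100, shift=0.35)
        out = call_dmrs(betas, sheet)
        sig = out[out["significant"]]
        assert set(sig["magnitude_class"]) <= {"H_DMR", "L_DMR"}
        assert (out.loc[~out["significant"], "magnitude_class"] == "NONE").all()

    def test_undefined_betas_rejected(self):
        sheet = make_samplesheet(2, 2)
        betas = pd.DataFrame(np.array([[0.1, np.nan, 0.3, 0.4]]), columns=sheet.index)
        with pytest.raises(ValueError, match="undefined"):
            call_dmrs(betas, sheet)

    def test_single_sample_group_rejected(self):
        sheet = make_samplesheet(1, 3)
        betas = pd.DataFrame(np.random.default_rng(0).random((3, 4)), columns=sheet.index)
        with pytest.raises(ValueError, match="2 samples"):
            call_dmrs(betas, sheet)

    def test_sorted_by_padj_then_abs_lfc(self, rng):
        betas, sheet = simulated_betas(rng, shift=0.15)
        out = call_dmrs(betas, sheet)
        p = out["p_adj"].to_numpy()
        assert (np.diff(p) >= -1e-15).all()


class TestMagnitude:
    def frame(self, lfc, significant):
        return pd.DataFrame({"lfc": [lfc], "significant": [significant]})

    def test_high_magnitude(self):
        assert classify_magnitude(self.frame(2.5, True))[0] == "H_DMR"
        assert classify_magnitude(self.frame(-2.5, True))[0] == "H_DMR"

    def test_low_magnitude(self):
        assert classify_magnitude(self.frame(1.0, True))[0] == "L_DMR"

    def test_boundary_value_is_low(self):
        # |lfc| must exceed the cut strictly
        assert classify_magnitude(self.frame(2.0, True))[0] == "L_DMR"

    def test_not_significant_is_none(self):
        assert classify_magnitude(self.frame(3.0, False))[0] == "NONE"


def test_dmr_config_validation():
    with pytest.raises(ValueError):
        DMRConfig(alpha=0)
    with pytest.raises(ValueError):
        DMRConfig(lfc_cut=3, h_cut=2)
    with pytest.raises(ValueError):
        DMRConfig(test_variant="wilcoxon")
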