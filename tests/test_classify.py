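import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rodsig
from rodsig.classify import (
    Thresholds,
    call_binding,
    classify_dhs,
    classify_polii,
    classify_rod_signature,
    compare_groups,
    dev_ratio,
    mean_plus_2sd,
    round_half_away,
    summarize_groups,
)
from rodsig.intervals import ValidationError


class TestCallBinding:
    @pytest.mark.parametrize("reads,expected", [(0, False), (1, True), (350, True)])
    def test_bimodal_rule(self, reads, expected):
        assert call_binding(reads) is expected

    def test_negative_is_error(self):
        with pytest.raises(ValidationError):
            call_binding(-1)

    @given(st.floats(min_value=0, max_value=1e6), st.floats(min_value=0, max_value=1e6))
    @settings(max_examples=50, derandomize=True)
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        if call_binding(lo):
            assert call_binding(hi)


class TestMeanPlus2SD:
    def test_examples(self):
        assert mean_plus_2sd([1, 1, 1]) == 1
        assert mean_plus_2sd([0, 10, 20]) == 30  # mean 10, sample SD 10

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.gamma(2.0, 30.0, size=rng.integers(5, 40))
            m = x.sum() / len(x)
            sd = np.sqrt(((x - m) ** 2).sum() / (len(x) - 1))
            assert mean_plus_2sd(x) == pytest.approx(m + 2 * sd)

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            mean_plus_2sd([1.0])


class TestGroupPartitions:
    @pytest.mark.parametrize("delta,expected", [
        (0.0, "none"), (-50.0, "none"), (100.0, "low"),
        (182.0, "low"), (183.0, "high"),
    ])
    def test_polii_groups(self, delta, expected):
        assert classify_polii(delta, 182.0) == expected

    @pytest.mark.parametrize("ratio,expected", [
        (0.8, "down"), (1.0, "up"), (1.2, "up"), (1.35, "up"), (1.5, "strong"),
    ])
    def test_dhs_groups(self, ratio, expected):
        assert classify_dhs(ratio, 1.35) == expected

    @given(st.floats(min_value=-1e4, max_value=1e4, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_polii_partition_total(self, delta):
        assert classify_polii(delta, 182.0) in ("none", "low", "high")

    @given(st.floats(min_value=1e-6, max_value=1e4, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_dhs_partition_total(self, ratio):
        assert classify_dhs(ratio, 1.35) in ("down", "up", "strong")


class TestDevRatio:
    def test_examples(self):
        assert dev_ratio(99, 9, 1) == 10
        assert dev_ratio(0, 0, 1) == 1
        with pytest.raises(ValidationError):
            dev_ratio(5, 0, 0)

    def test_cohort_mean_near_configured_center(self):
        """Rod-class developmental ratios concentrate near the configured 10.1."""
        cfg = rodsig.SimConfig(seed=0, n_genes_single=600, n_genes_two_tss=0,
                               n_genes_three_tss=0, n_planted_sites=0, n_chroms=3)
        sim = rodsig.simulate(cfg)
        fm = rodsig.build_feature_matrix(sim.tss_records, sim.tracks,
                                         chrom_sizes=sim.chrom_sizes)
        ratio = (fm.norm["H3K4me2_PN15"] + 1) / (fm.norm["H3K4me2_PN1"] + 1)
        assert ratio.mean() == pytest.approx(cfg.rod_k4_ratio, rel=0.10)


class TestRodSignatureRule:
    def _stats(self, **kw):
        row = dict(k4_ratio=10.1, k4_rd1_depleted=True, delta_polii=200.0,
                   dhs_ratio=2.0, crx_reads=400.0, nrl_reads=350.0,
                   crx_bound=True, nrl_bound=True)
        row.update(kw)
        return pd.DataFrame([row], index=["t"])

    def test_full_signature_is_rod(self):
        labels = classify_rod_signature(self._stats(), Thresholds())
        assert labels[0] == "rod"

    def test_flat_profile_is_common(self):
        stats = self._stats(k4_ratio=1.0, k4_rd1_depleted=False, dhs_ratio=0.5,
                            crx_reads=0.0, nrl_reads=0.0,
                            crx_bound=False, nrl_bound=False)
        assert classify_rod_signature(stats, Thresholds())[0] == "common"

    def test_tf_binding_not_required(self):
        """A quarter of genuine rod TSS lack CRX; the rule must not demand it."""
        stats = self._stats(crx_reads=0.0, nrl_reads=0.0,
                            crx_bound=False, nrl_bound=False)
        assert classify_rod_signature(stats, Thresholds())[0] == "rod"

    def test_missing_columns_is_error(self):
        with pytest.raises(ValidationError):
            classify_rod_signature(
                pd.DataFrame([{"k4_ratio": 10.0}]), Thresholds()
            )


class TestSummarizeGroups:
    @pytest.mark.parametrize("num,den,pct", [
        (55, 72, 76), (0, 72, 0), (68, 72, 94), (72, 107, 67), (2, 11, 18),
    ])
    def test_counts_and_rounding(self, num, den, pct):
        labels = ["x"] * num + ["y"] * (den - num)
        assert summarize_groups(labels, "x") == (num, pct)

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            summarize_groups([], "x")

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            labels = rng.choice(list("abcd"), size=int(rng.integers(1, 60)))
            total = sum(summarize_groups(labels, c)[1] for c in "abcd")
            assert abs(total - 100) <= 1

    def test_round_half_away(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3
        assert round_half_away(2.49) == 2


class TestCompareGroups:
    def test_identical_groups(self):
        assert compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert compare_groups([5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_separated_groups_against_formula(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        p = compare_groups(a, b)
        assert p < 1e-6
        # independent two-sample pooled-variance formula
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy.stats import t as tdist
        p_manual = 2 * tdist.sf(abs(t), na + nb - 2)
        assert p == pytest.approx(p_manual, rel=1e-9)

    def test_symmetric(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 2.5, 9.0]
        assert compare_groups(a, b) == compare_groups(b, a)


class TestClassifierEstimator:
    def test_fit_derives_thresholds_and_presets_override(self, fm_default):
        auto = rodsig.RodSignatureClassifier().fit(fm_default)
        assert auto.t_polii_ > 0 and auto.t_dhs_strong_ > 1.0
        preset = rodsig.RodSignatureClassifier(
            t_polii=182.0, t_dhs_strong=1.35
        ).fit(fm_default)
        assert (preset.t_polii_, preset.t_dhs_strong_) == (182.0, 1.35)

    def test_sklearn_param_interface(self):
        clf = rodsig.RodSignatureClassifier()
        params = clf.get_params()
        assert params["k4_ratio_min"] == 3.0
        clf.set_params(k4_ratio_min=4.0)
        assert clf.k4_ratio_min == 4.0

    def test_k4_developmental_ratio_separates_classes(self, sim_default,
                                                      fm_default, clf_default):
        """Rod TSS accumulate H3K4me2 ~4x more than common TSS, p << 0.05."""
        stats = clf_default.stats(fm_default)
        truth = sim_default.truth_labels().reindex(stats.index)
        rod = stats.loc[truth == "rod", "k4_ratio"]
        common = stats.loc[truth == "common", "k4_ratio"]
        assert rod.mean() > 2 * common.mean()
        assert compare_groups(rod, common) < 1e-3
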