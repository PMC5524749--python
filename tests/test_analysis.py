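"""The fluorescence pipeline: outliers, normalization, calling, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ligarray import (
    EfficiencyCoefficient,
    SpotCall,
    agreement,
    call_array,
    call_spot,
    detection_matrix,
    estimate_efficiency,
    normalize_if,
    prevalence,
    relative_abundance,
    remove_outliers,
    scale_by_efficiency,
    summarize_snr,
)
from ligarray.errors import (
    ControlMissingError,
    DegenerateReplicatesError,
    ParameterError,
    RegistryError,
    ShapeError,
)

from conftest import random_if_table


class TestRemoveOutliers:
    def test_tight_replicates_all_retained(self):
        vals = [100, 101, 99, 100]
        assert remove_outliers(vals) == vals

    def test_single_pass_rule_traced_on_skewed_quadruplicate(self):
        # mean 325; upper bound 812.5 removes 1000, lower bound 130 removes
        # 90/100/110 as well -> everything goes, which is an error by design
        with pytest.raises(DegenerateReplicatesError):
            remove_outliers([100, 110, 90, 1000])

    def test_moderate_outlier_survives_the_fold_window(self):
        # mean 87500: bounds [35000, 218750] retain all four values
        vals = [50000, 50000, 50000, 200000]
        assert remove_outliers(vals) == vals

    def test_order_preserved_after_removal(self):
        # mean 2250, window [900, 5625]: only the 6000 goes
        assert remove_outliers([1000.0, 1100.0, 900.0, 6000.0]) == [
            1000.0, 1100.0, 900.0
        ]
        assert remove_outliers([3.0, 2.0, 4.0]) == [3.0, 2.0, 4.0]

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            remove_outliers([])
        with pytest.raises(ParameterError):
            remove_outliers([1.0], fold=1.0)


def _table_with_zip63(zip63_ifs, probe_ifs=(4000, 4100, 3900, 4050)):
    rows = []
    for i, v in enumerate(zip63_ifs):
        rows.append(dict(array_id="A", row=0, col=i, zip_id="63",
                         role="ligation_control", replicate=i + 1,
                         IF=float(v), background=100.0))
    for i, v in enumerate(probe_ifs):
        rows.append(dict(array_id="A", row=1, col=i, zip_id="p1",
                         role="probe", replicate=i + 1,
                         IF=float(v), background=100.0))
    for i in range(6):
        rows.append(dict(array_id="A", row=2, col=i, zip_id="BLANK",
                         role="blank", replicate=i + 1,
                         IF=100.0 + i, background=100.0))
    return pd.DataFrame(rows)


class TestNormalization:
    def test_correction_factor_arithmetic(self):
        norm = normalize_if(_table_with_zip63([25000] * 4))
        assert norm.correction_factors["A"] == pytest.approx(2.0)
        z63 = norm.table.loc[norm.table.zip_id == "63", "IF"]
        assert z63.mean() == pytest.approx(50000.0)

    def test_background_rescaled_with_the_same_factor(self):
        norm = normalize_if(_table_with_zip63([25000] * 4))
        assert (norm.table.background == 200.0).all()

    def test_idempotent(self):
        once = normalize_if(_table_with_zip63([30000, 31000, 29500, 30200]))
        twice = normalize_if(once.table)
        assert twice.correction_factors["A"] == pytest.approx(1.0)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_missing_control_raises(self):
        table = _table_with_zip63([25000] * 4)
        with pytest.raises(ControlMissingError):
            normalize_if(table[table.zip_id != "63"])

    def test_retained_mean_hits_target_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            norm = normalize_if(random_if_table(rng))
            z63 = norm.table.loc[
                norm.table.role == "ligation_control", "IF"
            ].tolist()
            retained = remove_outliers(z63)
            assert np.mean(retained) == pytest.approx(50000.0, rel=1e-9)


class TestCallSpot:
    def test_strong_probe_called_with_expected_snr(self):
        probe = [5000, 5100, 4900, 5050]
        blank = [100, 95, 105, 110, 90, 100]
        call = call_spot(probe, blank)
        ref = stats.ttest_ind(probe, blank, equal_var=False,
                              alternative="greater")
        assert call.p_value == pytest.approx(float(ref.pvalue))
        assert call.significant
        assert call.snr == pytest.approx(np.mean(probe) / np.mean(blank))
        assert call.snr == pytest.approx(50.125, abs=1e-9)

    def test_probe_equal_to_blank_mean_has_unit_snr(self):
        call = call_spot([100.0] * 4, [90, 95, 100, 105, 110, 100])
        assert call.snr == pytest.approx(1.0)
        assert not call.significant

    def test_null_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        n_sig = 0
        n_trials = 1500
        for _ in range(n_trials):
            probe = rng.normal(500, 50, size=4)
            blank = rng.normal(500, 50, size=6)
            if call_spot(probe, blank).significant:
                n_sig += 1
        assert 0.004 <= n_sig / n_trials <= 0.018

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(DegenerateReplicatesError):
            call_spot([100.0], [90, 95, 100, 105, 110, 100])

    def test_scale_invariance_of_p_and_snr(self):
        rng = np.random.default_rng(5)
        probe = rng.normal(3000, 200, size=4)
        blank = rng.normal(400, 40, size=6)
        a = call_spot(probe, blank)
        b = call_spot(probe * 7.3, blank * 7.3)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.snr == pytest.approx(b.snr)


class TestCallArray:
    def test_calls_probes_against_own_array_blanks(self):
        table = _table_with_zip63([25000] * 4)
        norm = normalize_if(table)
        calls = call_array(norm)
        assert len(calls) == 1
        assert [c.target for c in calls[0].probe_calls] == ["p1"]
        assert calls[0].probe_calls[0].significant
        assert [c.target for c in calls[0].control_calls] == ["63"]

    def test_empty_spots_ignored(self):
        table = _table_with_zip63([25000] * 4)
        extra = pd.DataFrame([dict(array_id="A", row=5, col=0, zip_id="EMPTY",
                                   role="empty", replicate=0, IF=90.0,
                                   background=100.0)])
        calls = call_array(normalize_if(pd.concat([table, extra], ignore_index=True)))
        assert [c.target for c in calls[0].probe_calls] == ["p1"]


class TestSnrSummary:
    def test_single_row_collapses(self):
        s = summarize_snr([("x", 12.0, 1.1)])
        assert s.s_mean == s.s_min == s.s_max == 12.0
        assert s.ns_mean == 1.1

    def test_spotcalls_split_by_significance(self):
        calls = [
            SpotCall("a", 5000, 1e-5, 50.0, True, 4),
            SpotCall("b", 120, 0.4, 1.2, False, 4),
            SpotCall("c", 130, 0.2, 1.4, False, 4),
        ]
        s = summarize_snr(calls)
        assert s.s_mean == 50.0 and s.n_significant == 1
        assert s.ns_mean == 1.3 and s.n_nonsignificant == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            summarize_snr([])


def _call(snr, sig=True):
    return SpotCall("t", snr * 100, 1e-4 if sig else 0.5, snr, sig, 4)


class TestEfficiency:
    def test_proportional_series_has_unit_correlation(self):
        series = [(ng, _call(5.0 * ng)) for ng in (8, 6, 4, 2, 1)]
        eff = estimate_efficiency(series)
        assert eff.pearson_r == pytest.approx(1.0)
        assert eff.efficiency == pytest.approx(5.0)

    def test_efficiency_is_mean_snr_per_ng(self):
        series = [(8, _call(40.0)), (4, _call(20.0)), (1, _call(5.0))]
        assert estimate_efficiency(series).efficiency == pytest.approx(5.0)

    def test_too_few_significant_points_rejected(self):
        with pytest.raises(ParameterError):
            estimate_efficiency([(8, _call(40.0)), (4, _call(20.0, sig=False))])

    def test_scaling_equalizes_probes_with_different_efficiencies(self):
        values = {"a": 8000.0, "b": 16000.0}
        effs = {"a": EfficiencyCoefficient("a", 2.0, 1.0, 5),
                "b": EfficiencyCoefficient("b", 4.0, 1.0, 5)}
        scaled = scale_by_efficiency(values, effs)
        assert scaled["a"] == pytest.approx(scaled["b"])

    def test_unit_efficiency_is_identity_and_missing_passthrough(self):
        values = {"a": 7.0, "b": 9.0}
        scaled = scale_by_efficiency(values, {"a": 1.0})
        assert scaled == {"a": 7.0, "b": 9.0}
        with pytest.raises(ParameterError):
            scale_by_efficiency({"a": 1.0}, {"a": 0.0})


def _calls_from_bits(bits):
    return [
        SpotCall(f"t{j}", 1000.0, 1e-4 if b else 0.5, 10.0 if b else 1.0,
                 bool(b), 4)
        for j, b in enumerate(bits)
    ]


class TestDetectionAndPrevalence:
    def test_prevalence_from_site_counts(self):
        # 8/10 saliva, 5/10 lingual, 2/10 plaque, 0/6 caps -> 15/36 -> 42%
        # 0/10, 0/10, 5/10 plaque, 4/6 caps -> 9/36 -> 25%
        samples = []
        site_counts = {"saliva": (10, 8, 0), "lingual": (10, 5, 0),
                       "plaque": (10, 2, 5), "cap": (6, 0, 4)}
        i = 0
        for site, (n, k1, k2) in site_counts.items():
            for j in range(n):
                bits = [int(j < k1), int(j < k2), 1]
                samples.append((f"{site}_{j}", _calls_from_bits(bits)))
                i += 1
        dm = detection_matrix(samples)
        prev = prevalence(dm)
        assert prev["t0"] == 42
        assert prev["t1"] == 25
        assert prev["t2"] == 100

    def test_registry_mismatch_rejected(self):
        a = ("s1", _calls_from_bits([1, 0]))
        b = ("s2", _calls_from_bits([1, 0, 1]))
        with pytest.raises(RegistryError):
            detection_matrix([a, b])

    def test_grouped_prevalence(self):
        samples = [("s1", _calls_from_bits([1])), ("s2", _calls_from_bits([0])),
                   ("l1", _calls_from_bits([1])), ("l2", _calls_from_bits([1]))]
        dm = detection_matrix(samples)
        by_site = prevalence(dm, groups={"s1": "saliva", "s2": "saliva",
                                         "l1": "lingual", "l2": "lingual"})
        assert by_site.loc["saliva", "t0"] == 50
        assert by_site.loc["lingual", "t0"] == 100


class TestAgreement:
    def test_identical_profiles(self):
        a = np.ones((4, 22))
        assert agreement(a, a.copy()) == 100.0

    def test_two_discordant_of_88(self):
        a = np.zeros(88)
        b = a.copy()
        b[:2] = 1
        assert agreement(a, b) == 97.7

    def test_complementary_profiles(self):
        a = np.zeros(10)
        assert agreement(a, 1 - a) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            agreement(np.zeros(3), np.zeros(4))


class TestRelativeAbundance:
    def test_two_target_split(self):
        mean_if = pd.DataFrame({"a": [3000.0], "b": [1000.0]}, index=["s1"])
        sig = pd.DataFrame({"a": [True], "b": [True]}, index=["s1"])
        ab = relative_abundance(mean_if, sig)
        assert ab.loc["s1", "a"] == pytest.approx(75.0)
        assert ab.loc["s1", "b"] == pytest.approx(25.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(8)
        mean_if = pd.DataFrame(rng.uniform(100, 9000, size=(5, 6)),
                               index=[f"s{i}" for i in range(5)],
                               columns=[f"t{j}" for j in range(6)])
        sig = pd.DataFrame(rng.random((5, 6)) > 0.3,
                           index=mean_if.index, columns=mean_if.columns)
        groups = {f"s{i}": f"g{i % 2}" for i in range(5)}
        ab = relative_abundance(mean_if, sig, groups=groups)
        for _, row in ab.iterrows():
            assert row.sum() == pytest.approx(100.0) or row.sum() == 0.0

    def test_nonsignificant_targets_contribute_zero(self):
        mean_if = pd.DataFrame({"a": [3000.0], "b": [1000.0]}, index=["s1"])
        sig = pd.DataFrame({"a": [True], "b": [False]}, index=["s1"])
        ab = relative_abundance(mean_if, sig)
        assert ab.loc["s1", "a"] == pytest.approx(100.0)
        assert ab.loc["s1", "b"] == 0.0

    def test_group_without_detections_is_all_zero(self):
        mean_if = pd.DataFrame({"a": [3000.0]}, index=["s1"])
        sig = pd.DataFrame({"a": [False]}, index=["s1"])
        ab = relative_abundance(mean_if, sig)
        assert (ab.loc["s1"] == 0.0).all()
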