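"""QC gate, threshold derivation, positivity calling, LJ charts, LOD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctfusion.calling import (
    FusionCallSet,
    NotEvaluableError,
    call_fusions,
    derive_thresholds,
    geometric_mean_hk,
    levey_jennings,
    lod_from_dilution,
)
from ctfusion.simulate import AssayTruth, simulate_count_profile

ALKV1 = "ALK_EML4_E13:A20"


def _thresholds(make_profile, panel, neg_counts=(5, 8, 11), **kwargs):
    negs = [make_profile(sample_id=f"N{i}", **{p: c for p in panel.fusion_ids})
            for i, c in enumerate(neg_counts)]
    return derive_thresholds(negs, panel, **kwargs)


class TestQcGate:
    @pytest.mark.parametrize(
        "hk, expected_gm, evaluable",
        [
            ((100, 200, 400), 200.0, True),   # (100*200*400)^(1/3) = 200 exactly
            ((30, 30, 30), 30.0, False),      # boundary: gate is strictly > 30
            ((0, 500, 500), 0.0, False),      # zero annihilates the product
            ((31, 31, 31), 31.0, True),
        ],
    )
    def test_geometric_mean_and_gate(self, make_profile, panel, hk, expected_gm, evaluable):
        prof = make_profile(GAPDH=hk[0], MRPL19=hk[1], PSMC4=hk[2])
        qc = geometric_mean_hk(prof, panel)
        assert qc.hk_geomean == pytest.approx(expected_gm)
        assert qc.evaluable is evaluable

    def test_missing_hk_count_errors(self, make_profile, panel):
        prof = make_profile()
        del prof.counts["GAPDH"]
        with pytest.raises(ValueError, match="GAPDH"):
            geometric_mean_hk(prof, panel)

    def test_every_profile_gets_exactly_one_verdict(self, make_profile, panel):
        """The QC gate is total: evaluable is a strict boolean partition."""
        for hk in ((29, 30, 31), (1, 1, 1), (1000, 1000, 1000)):
            qc = geometric_mean_hk(make_profile(GAPDH=hk[0], MRPL19=hk[1], PSMC4=hk[2]), panel)
            assert qc.evaluable in (True, False)


class TestDeriveThresholds:
    def test_mean_plus_six_sd(self, make_profile, panel):
        """Negatives (5, 8, 11): mean 8, sample SD 3, threshold 26."""
        thr = _thresholds(make_profile, panel)
        assert thr.means[ALKV1] == pytest.approx(8.0)
        assert thr.sds[ALKV1] == pytest.approx(3.0)
        assert thr.thresholds[ALKV1] == pytest.approx(26.0)

    def test_degenerate_identical_negatives(self, make_profile, panel):
        thr = _thresholds(make_profile, panel, neg_counts=(7, 7, 7))
        assert thr.sds[ALKV1] == 0.0
        assert thr.thresholds[ALKV1] == pytest.approx(7.0)

    def test_fewer_than_two_profiles_rejected(self, make_profile, panel):
        with pytest.raises(ValueError, match=">= 2"):
            derive_thresholds([make_profile()], panel)

    def test_non_evaluable_profiles_excluded(self, make_profile, panel):
        """A QC-failing profile never contributes to thresholds."""
        good = [make_profile(sample_id=f"G{i}", **{ALKV1: c}) for i, c in enumerate((5, 8, 11))]
        bad = make_profile(sample_id="BAD", GAPDH=1, MRPL19=1, PSMC4=1, **{ALKV1: 10_000})
        thr = derive_thresholds(good + [bad], panel)
        assert "BAD" not in thr.negative_cohort_ids
        assert thr.thresholds[ALKV1] == pytest.approx(26.0)

    def test_background_subtract_mode(self, make_profile, panel):
        floor = _thresholds(make_profile, panel, background_mode="floor")
        sub = _thresholds(make_profile, panel, background_mode="subtract")
        assert floor.background_subtract == 0.0
        assert sub.background_subtract == pytest.approx(5.0)  # NEG_* counts are 5
        assert sub.thresholds[ALKV1] == pytest.approx(floor.thresholds[ALKV1] - 5.0)


class TestCallFusions:
    def test_clinical_scale_positive(self, make_profile, panel):
        """A count of 6756 against a threshold of 26 is an unambiguous call."""
        thr = _thresholds(make_profile, panel)
        calls = call_fusions(make_profile(**{ALKV1: 6756}), thr, panel)
        assert calls.probe_calls[ALKV1] is True
        assert calls.overall_alteration == ALKV1
        assert calls.overall_gene == "ALK"

    def test_counts_at_threshold_are_negative(self, make_profile, panel):
        """Strict inequality: a count exactly at mean+6SD stays negative."""
        thr = _thresholds(make_profile, panel)
        exact = {pid: int(thr.thresholds[pid]) for pid in panel.fusion_ids}
        calls = call_fusions(make_profile(**exact), thr, panel)
        assert not any(calls.probe_calls.values())
        assert calls.overall_alteration == "none"

    @pytest.mark.parametrize("skip, wt, expected", [(30, 300, "negative"), (510, 300, "positive")])
    def test_met_ratio_calls(self, make_profile, panel, skip, wt, expected):
        """Skip/wt of 0.1 is negative; 1.7 is positive (cutoff 1.0, strict)."""
        thr = _thresholds(make_profile, panel)
        calls = call_fusions(make_profile(MET_delta14=skip, MET_wt=wt), thr, panel)
        assert calls.met_ratio == pytest.approx(skip / wt)
        assert calls.met_call == expected

    def test_met_ratio_at_cutoff_is_negative(self, make_profile, panel):
        thr = _thresholds(make_profile, panel)
        calls = call_fusions(make_profile(MET_delta14=300, MET_wt=300), thr, panel)
        assert calls.met_ratio == pytest.approx(1.0)
        assert calls.met_call == "negative"

    def test_zero_wt_met_is_non_evaluable_not_positive(self, make_profile, panel):
        thr = _thresholds(make_profile, panel)
        calls = call_fusions(make_profile(MET_wt=0, MET_delta14=50), thr, panel)
        assert calls.met_ratio is None
        assert calls.met_call == "non_evaluable"
        assert calls.overall_alteration == "none"

    def test_non_evaluable_profile_refused(self, make_profile, panel):
        thr = _thresholds(make_profile, panel)
        bad = make_profile(GAPDH=1, MRPL19=1, PSMC4=1)
        with pytest.raises(NotEvaluableError, match="failed QC"):
            call_fusions(bad, thr, panel)

    def test_tie_resolution_largest_margin_wins(self, make_profile, panel):
        """Two positive genes: the larger count/threshold ratio is reported,
        both stay listed."""
        thr = _thresholds(make_profile, panel)
        ros1 = "ROS1_CD74_C6:R32"
        calls = call_fusions(make_profile(**{ALKV1: 100, ros1: 5000}), thr, panel)
        assert calls.overall_alteration == ros1
        assert set(calls.positives) == {ALKV1, ros1}

    @given(base_count=st.integers(min_value=0, max_value=10_000),
           extra=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_counts(self, base_count, extra):
        """Raising a probe's count never flips a positive call to negative."""
        from ctfusion import default_panel
        panel = default_panel()

        def profile(count):
            counts = {}
            for p in panel:
                counts[p.probe_id] = {
                    "housekeeping": 200, "met_wt": 300, "met_skip": 30
                }.get(p.probe_class, 5)
            counts[ALKV1] = count
            from ctfusion import CountProfile
            return CountProfile("s", counts)

        negs = [profile(c) for c in (5, 8, 11)]
        thr = derive_thresholds(negs, panel)
        base = call_fusions(profile(base_count), thr, panel)
        raised = call_fusions(profile(base_count + extra), thr, panel)
        if base.probe_calls[ALKV1]:
            assert raised.probe_calls[ALKV1]


class TestLeveyJennings:
    def test_constant_replicates(self):
        stats = levey_jennings([10] * 6)
        assert stats.sd == 0.0 and not any(stats.out_of_control)

    def test_limits(self):
        """(8,9,10,11,12,10): center 10, sample SD sqrt(2), 3SD at 10 +/- 3*sqrt(2)."""
        stats = levey_jennings([8, 9, 10, 11, 12, 10])
        assert stats.center == pytest.approx(10.0)
        assert stats.sd == pytest.approx(math.sqrt(2))
        assert stats.control_limits == pytest.approx((10 - 3 * math.sqrt(2), 10 + 3 * math.sqrt(2)))
        assert not any(stats.out_of_control)

    def test_single_outlier_flagged_against_reference_limits(self):
        """A run 4 SD beyond the established QC mean violates the 1_3s rule;
        self-derived limits on the same six values cannot flag it, since the
        outlier inflates the batch SD (max |z| is (n-1)/sqrt(n) ~ 2.04 at n=6)."""
        values = [10, 10.1, 9.9, 10.05, 9.95, 10.4]
        stats = levey_jennings(values, reference_center=10.0, reference_sd=0.1)
        assert stats.out_of_control == [False] * 5 + [True]
        assert not any(levey_jennings(values).out_of_control)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            levey_jennings([10])


def _callsets(detected_flags):
    out = []
    for i, det in enumerate(detected_flags):
        out.append(
            FusionCallSet(
                sample_id=f"r{i}", evaluable=True,
                probe_calls={ALKV1: det},
                positives=[ALKV1] if det else [],
                overall_alteration=ALKV1 if det else "none",
                overall_gene="ALK" if det else "none",
            )
        )
    return out


class TestLod:
    def test_smallest_fully_detected_level(self):
        bank = {
            1e-2: _callsets([True] * 10),
            1e-3: _callsets([True] * 10),
            1e-4: _callsets([True] * 3 + [False] * 7),
        }
        res = lod_from_dilution(bank, ALKV1)
        assert res.tumor_fraction == 1e-3
        assert res.detection_rates == {1e-2: 1.0, 1e-3: 1.0, 1e-4: pytest.approx(0.3)}

    def test_no_level_passes(self):
        bank = {1e-2: _callsets([False] * 5), 1e-3: _callsets([False] * 5)}
        res = lod_from_dilution(bank, ALKV1)
        assert res.tumor_fraction is None and not res.defined

    def test_rna_concentration_conversion(self):
        bank = {1e-2: _callsets([True] * 5), 1e-3: _callsets([False] * 5)}
        res = lod_from_dilution(bank, ALKV1, rna_conc_pg_per_ul=10_000.0)
        assert res.rna_pg_per_ul == pytest.approx(100.0)

    def test_needs_two_levels(self):
        with pytest.raises(ValueError, match=">= 2"):
            lod_from_dilution({1e-2: _callsets([True])}, ALKV1)


class TestNullCalibration:
    def test_control_samples_rarely_called(self, panel, config):
        """Thresholds from an independent simulated negative cohort call
        fewer than 1% of fresh control samples positive (the clinical
        benchmark is 0 of 16 controls across all 23 probes)."""
        rng = np.random.default_rng(20)
        fp_samples = n_nulls = 0
        for _ in range(4):  # average over threshold draws
            negs = [
                simulate_count_profile(AssayTruth(f"n{i}", "none", 0.0), config, rng=rng)
                for i in range(16)
            ]
            thr = derive_thresholds(negs, panel)
            for i in range(250):
                prof = simulate_count_profile(AssayTruth(f"z{i}", "none", 0.0), config, rng=rng)
                fp_samples += call_fusions(prof, thr, panel).detected
                n_nulls += 1
        assert fp_samples / n_nulls < 0.01
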