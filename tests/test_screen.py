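"""Tests for assay quality, hit calling and screen summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mcakscreen.fret import compute_plate_ratios, plate_baselines
from mcakscreen.screen import (
    HitCall,
    HitClass,
    assay_quality,
    call_fret_plate,
    call_fret_well,
    call_image_well,
    confirm_hits,
    counter_screen_filter,
    cv_percent,
    dilution_concentration,
    hit_rate,
    hit_set,
    intersect_replicates,
    molar_ratio_integer,
    summarize_screen,
    z_prime,
)
from mcakscreen.synth import FretEffectModel, simulate_duplicate_screen


class TestZPrime:
    def test_zero_sds_give_perfect_assay(self):
        assert z_prime([2.0, 2.0, 2.0], [1.0, 1.0, 1.0]) == 1.0

    def test_textbook_arithmetic_case(self):
        # mean 2.0 / SD 0.1 versus mean 1.0 / SD 0.1: 1 - 0.6/1 = 0.4
        pc = [1.9, 2.0, 2.1]  # sample SD 0.1
        nc = [0.9, 1.0, 1.1]
        assert z_prime(pc, nc) == pytest.approx(0.4)

    def test_equal_means_undefined(self):
        assert math.isnan(z_prime([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            z_prime([1.0], [2.0, 2.1])

    def test_never_exceeds_one_and_improves_with_tighter_controls(self, rng):
        """Z' <= 1 always, and shrinking control noise monotonically
        improves the expected Z' over an SD grid."""
        prev = -np.inf
        for sd in (0.2, 0.1, 0.05, 0.02, 0.01):
            zs = []
            for _ in range(30):
                pc = rng.normal(1.64, sd, 8)
                nc = rng.normal(1.34, sd, 8)
                z = z_prime(pc, nc)
                assert z <= 1.0
                zs.append(z)
            mean_z = np.mean(zs)
            assert mean_z > prev
            prev = mean_z


class TestCvPercent:
    def test_constant_values_have_zero_cv(self):
        assert cv_percent([10.0, 10.0, 10.0]) == 0.0

    def test_sd_one_mean_ten_gives_ten_percent(self):
        assert cv_percent([9.0, 10.0, 11.0]) == pytest.approx(10.0)

    def test_zero_mean_undefined(self):
        assert math.isnan(cv_percent([-1.0, 1.0]))

    def test_quality_bundle_reports_both(self):
        q = assay_quality([1.9, 2.0, 2.1], [0.9, 1.0, 1.1])
        assert q.z_prime == pytest.approx(0.4)
        assert q.cv_percent == pytest.approx(5.0)


class TestImageCalls:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (55.0, HitClass.INHIBITOR),
            (50.0, HitClass.NONE),  # strict >
            (49.9, HitClass.NONE),
            (10.0, HitClass.NONE),  # strict <
            (9.9, HitClass.ACTIVATOR),
            (0.0, HitClass.ACTIVATOR),
        ],
    )
    def test_polymer_remaining_thresholds_are_strict(self, pct, expected):
        assert call_image_well(pct) is expected


class TestFretCalls:
    def test_antibody_like_drop_is_inhibitor(self):
        cls, change = call_fret_well(1.34, 1.64)
        assert cls is HitClass.INHIBITOR
        assert change == pytest.approx(-18.3, abs=0.05)

    def test_fifteen_percent_boundary_is_inclusive(self):
        cls, change = call_fret_well(1.394, 1.64)  # computes to -15.0%
        assert cls is HitClass.INHIBITOR
        assert change <= -15.0
        # the boundary semantics ("or more" includes equality) checked at
        # an exactly representable threshold
        assert call_fret_well(1.125, 1.0, threshold_pct=12.5)[0] is HitClass.ACTIVATOR
        assert call_fret_well(0.875, 1.0, threshold_pct=12.5)[0] is HitClass.INHIBITOR

    def test_small_change_is_none(self):
        cls, _ = call_fret_well(1.60, 1.64)
        assert cls is HitClass.NONE

    def test_invalid_ratio_yields_none_with_nan_metric(self):
        cls, change = call_fret_well(math.nan, 1.64)
        assert cls is HitClass.NONE and math.isnan(change)

    @given(st.floats(0.5, 3.0), st.floats(1.0, 2.0))
    def test_call_is_pure_function_of_metric(self, ratio, baseline):
        a = call_fret_well(ratio, baseline)
        b = call_fret_well(ratio, baseline)
        assert a == b


def _call(cid, cls, assay="FRET", rep=0):
    return HitCall(cid, assay, cls, 0.0, rep)


class TestReplicatesAndCounterScreen:
    def test_intersection_matches_worked_example(self):
        """Six hits per replicate with three shared compounds yields a
        three-compound duplicate-confirmed set."""
        rep1 = {c: _call(c, HitClass.INHIBITOR) for c in "abcdef"}
        rep2 = {c: _call(c, HitClass.INHIBITOR, rep=1) for c in "abcxyz"}
        rep1.update({c: _call(c, HitClass.NONE) for c in "xyz"})
        rep2.update({c: _call(c, HitClass.NONE, rep=1) for c in "def"})
        assert intersect_replicates(rep1, rep2) == {"a", "b", "c"}

    def test_disjoint_and_identical_replicates(self):
        rep1 = {c: _call(c, HitClass.INHIBITOR) for c in "ab"}
        rep2 = {c: _call(c, HitClass.NONE, rep=1) for c in "ab"}
        assert intersect_replicates(rep1, rep2) == set()
        assert intersect_replicates(rep1, rep1) == {"a", "b"}

    def test_opposite_classes_do_not_intersect(self):
        rep1 = {"a": _call("a", HitClass.INHIBITOR)}
        rep2 = {"a": _call("a", HitClass.ACTIVATOR, rep=1)}
        assert intersect_replicates(rep1, rep2) == set()

    def test_intersection_is_symmetric(self):
        rep1 = {"a": _call("a", HitClass.INHIBITOR), "b": _call("b", HitClass.NONE)}
        rep2 = {"a": _call("a", HitClass.INHIBITOR), "b": _call("b", HitClass.ACTIVATOR)}
        assert intersect_replicates(rep1, rep2) == intersect_replicates(rep2, rep1)

    def test_counter_screen_keeps_clean_hits(self):
        hits = {f"c{i}" for i in range(14)}
        fcp = {c: _call(c, HitClass.NONE) for c in hits}
        assert counter_screen_filter(hits, fcp) == hits

    def test_counter_screen_removes_fluorescence_artifacts(self):
        hits = {"a", "b"}
        fcp = {"a": _call("a", HitClass.INHIBITOR), "b": _call("b", HitClass.NONE)}
        assert counter_screen_filter(hits, fcp) == {"b"}
        assert counter_screen_filter(set(), fcp) == set()

    def test_confirmation_requires_rescreen_and_counter_screen(self):
        primary = {"a", "b", "c"}
        rescreen = {
            "a": _call("a", HitClass.INHIBITOR),
            "b": _call("b", HitClass.NONE),
            "c": _call("c", HitClass.INHIBITOR),
        }
        fcp = {"c": _call("c", HitClass.ACTIVATOR)}
        assert confirm_hits(primary, rescreen, fcp) == {"a"}


class TestAssaySetupArithmetic:
    @pytest.mark.parametrize(
        "n_hits,n,expected", [(38, 3000, 1.3), (3, 1280, 0.2), (0, 500, 0.0)]
    )
    def test_hit_rate_rounding(self, n_hits, n, expected):
        assert hit_rate(n_hits, n) == expected

    def test_hit_rate_requires_positive_denominator(self):
        with pytest.raises(ValueError):
            hit_rate(1, 0)

    @pytest.mark.parametrize(
        "stock,vol,final,expected",
        [(25.0, 10.9, 30.0, 9.08), (2.5, 20.0, 55.0, 0.91), (7.0, 5.0, 5.0, 7.0)],
    )
    def test_dilution_concentration(self, stock, vol, final, expected):
        assert dilution_concentration(stock, vol, final) == expected

    def test_dilution_volume_ordering_enforced(self):
        with pytest.raises(ValueError):
            dilution_concentration(25.0, 30.0, 10.0)

    def test_molar_ratio_integer_part(self):
        assert molar_ratio_integer(0.2e-6, 3e-9) == 66
        assert molar_ratio_integer(5.0, 5.0) == 1
        with pytest.raises(ValueError):
            molar_ratio_integer(0.2e-6, 0.0)


class TestSimulatedScreen:
    def test_planted_hits_recovered_and_false_positives_match_tail(self):
        """With strong planted effects every true hit is called in both
        replicates, and the per-replicate false-positive count matches
        the two-sided normal tail prediction within binomial error."""
        model = FretEffectModel(fmcak=(1.64, 0.06))  # well noise wide enough to test tails
        planted = {f"CB{i:05d}" for i in (7, 80, 200, 290, 340)}
        sim = simulate_duplicate_screen(352, planted, effect_size=0.6, seed=11, model=model)
        rep_calls = []
        for rep in range(2):
            calls = {}
            for (readings, _), lay in zip(sim.replicates[rep], sim.layouts):
                ratios = compute_plate_ratios(readings, lay, background=model.background)
                baselines = plate_baselines(ratios, lay)
                calls.update(call_fret_plate(ratios, baselines, replicate=rep))
            rep_calls.append(calls)
        confirmed = intersect_replicates(*rep_calls)
        assert planted <= confirmed
        # false positives: |z| >= 0.15*mean/sd per side, n non-hit compounds
        sd_rel = 0.06 / 1.64
        p_tail = 2 * stats.norm.sf(0.15 / sd_rel)
        n_null = 352 - len(planted)
        expected = n_null * p_tail
        spread = 3 * math.sqrt(n_null * p_tail * (1 - p_tail))
        for calls in rep_calls:
            fp = len(hit_set(calls) - planted)
            assert abs(fp - expected) <= max(spread, 3.0)

    def test_call_permutation_invariance(self):
        """Classification depends only on each well's metric, never on
        well order."""
        model = FretEffectModel()
        sim = simulate_duplicate_screen(352, {"CB00005"}, effect_size=0.6, seed=3, model=model)
        readings, _ = sim.replicates[0][0]
        lay = sim.layouts[0]
        ratios = compute_plate_ratios(readings, lay, background=model.background)
        baselines = plate_baselines(ratios, lay)
        calls_fwd = call_fret_plate(ratios, baselines)
        shuffled = ratios.sample(frac=1.0, random_state=0).reset_index(drop=True)
        calls_shuf = call_fret_plate(shuffled, baselines)
        assert calls_fwd == calls_shuf


class TestSummary:
    def test_summary_counts_and_rates(self):
        image = {c: _call(c, HitClass.INHIBITOR, "IMAGE") for c in "abcdef"}
        image.update({c: _call(c, HitClass.NONE, "IMAGE") for c in "xyz"})
        fret = {c: _call(c, HitClass.INHIBITOR) for c in "abq"}
        summary = summarize_screen({"IMAGE": image, "FRET": fret}, n_compounds=3000)
        assert summary.hits_per_assay == {"IMAGE": 6, "FRET": 3}
        assert summary.overlap == 2
        assert summary.hit_rate_percent["IMAGE"] == 0.2
        frame = summary.to_frame()
        assert set(frame["assay"]) == {"IMAGE", "FRET"}
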