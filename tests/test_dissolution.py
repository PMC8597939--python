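import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bekit.dissolution import (
    DissolutionProfile,
    FitFactors,
    HplcReleaseInput,
    SamplingScheme,
    Verdict,
    compute_fit_factors,
    correct_cumulative,
    fit_factor_f1,
    fit_factor_f2,
    percent_released_conc,
    percent_released_hplc,
    release_rate,
    similarity_verdict,
)

profiles_strategy = st.lists(
    st.floats(min_value=0.0, max_value=110.0), min_size=1, max_size=10
).filter(lambda xs: sum(xs) > 0)


class TestPercentReleased:
    @pytest.mark.parametrize(
        "conc, tmax, expected",
        [(1.32, 1.5, 88.0), (0.0, 1.5, 0.0), (1.5, 1.5, 100.0), (0.89, 1.5, 59.33333333)],
    )
    def test_concentration_route(self, conc, tmax, expected):
        assert percent_released_conc(conc, tmax) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percent_released_conc(1.0, 0.0)
        with pytest.raises(ValueError):
            percent_released_conc(-0.1, 1.5)

    def test_hplc_route_worked_example(self):
        # equal areas, Ws = 30 mg, Wu = 100 % -> 30*100/(20*1.5) = 100 %
        inp = HplcReleaseInput(
            sample_area=1000.0, standard_average_area=1000.0, ws_mg=30.0, wu_pct=100.0
        )
        assert percent_released_hplc(inp) == pytest.approx(100.0)

    def test_hplc_route_zero_and_linearity(self):
        base = dict(standard_average_area=5000.0, ws_mg=30.0, wu_pct=99.0)
        assert percent_released_hplc(HplcReleaseInput(sample_area=0.0, **base)) == 0.0
        full = percent_released_hplc(HplcReleaseInput(sample_area=4200.0, **base))
        half = percent_released_hplc(HplcReleaseInput(sample_area=2100.0, **base))
        assert half == pytest.approx(full / 2)

    def test_hplc_invalid_denominator(self):
        with pytest.raises(ValueError):
            HplcReleaseInput(sample_area=1.0, standard_average_area=0.0, ws_mg=30, wu_pct=100)


class TestWithdrawalCorrection:
    def test_hand_summed_series(self):
        scheme = SamplingScheme(vessel_volume_ml=1000, sample_volume_ml=3)
        raw = [(15, 1.5), (30, 1.5), (45, 1.5), (60, 1.5)]
        corrected = correct_cumulative(raw, scheme)
        added = [c - 1.5 for _, c in corrected]
        # (3/1000)*cumulative prior concentration: 0, 0.0045, 0.009, 0.0135
        assert added == pytest.approx([0.0, 0.0045, 0.009, 0.0135])

    def test_disabled_is_identity(self):
        scheme = SamplingScheme(1000, 3, replace_with_medium=False)
        raw = [(15, 0.9), (30, 1.2)]
        assert correct_cumulative(raw, scheme) == raw

    def test_single_point_unchanged(self):
        scheme = SamplingScheme(1000, 3)
        assert correct_cumulative([(15, 0.7)], scheme) == [(15.0, 0.7)]

    def test_never_decreases_and_vanishes_with_small_fraction(self):
        raw = [(t, c) for t, c in zip([10, 20, 30], [0.5, 1.0, 1.4])]
        big = correct_cumulative(raw, SamplingScheme(100, 3))
        tiny = correct_cumulative(raw, SamplingScheme(1_000_000, 3))
        assert all(b >= r for (_, b), (_, r) in zip(big, raw))
        assert [c for _, c in tiny] == pytest.approx([c for _, c in raw], rel=1e-4)


class TestFitFactors:
    def test_identical_profiles(self):
        r = [12.0, 45.0, 78.0, 95.0]
        assert fit_factor_f1(r, r) == 0.0
        assert fit_factor_f2(r, r) == pytest.approx(100.0)

    def test_printed_thirty_forty_five_minute_values(self):
        # R=(88,100), T=(60,67): f1 = 100*(28+33)/188; f2 from MSD 936.5
        assert fit_factor_f1([88, 100], [60, 67]) == pytest.approx(100 * 61 / 188)
        expected_f2 = 50 * (2 - 0.5 * math.log10(1 + (28**2 + 33**2) / 2))
        assert fit_factor_f2([88, 100], [60, 67]) == pytest.approx(expected_f2)
        assert expected_f2 == pytest.approx(25.70, abs=0.01)

    def test_single_point_f1(self):
        assert fit_factor_f1([50.0], [40.0]) == pytest.approx(20.0)

    def test_f2_is_50_at_msd_99(self):
        # the conventional cutoff f2 = 50 arises exactly at MSD = 99
        assert fit_factor_f2([10.0], [10.0 + math.sqrt(99.0)]) == pytest.approx(50.0)

    def test_length_mismatch_and_zero_reference(self):
        with pytest.raises(ValueError):
            fit_factor_f1([1, 2], [1])
        with pytest.raises(ValueError):
            fit_factor_f2([1, 2], [1])
        with pytest.raises(ValueError):
            fit_factor_f1([0.0, 0.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(r=profiles_strategy)
    def test_identity_properties(self, r):
        assert fit_factor_f1(r, r) == 0.0
        assert fit_factor_f2(r, r) == pytest.approx(100.0)

    def test_monotone_in_uniform_offset(self):
        r = np.array([20.0, 50.0, 80.0, 95.0])
        f2s = [fit_factor_f2(r, r + d) for d in (0, 2, 5, 10, 20)]
        f1s = [fit_factor_f1(r, r + d) for d in (0, 2, 5, 10, 20)]
        assert all(a > b for a, b in zip(f2s, f2s[1:]))
        assert all(a < b for a, b in zip(f1s, f1s[1:]))

    def test_reorder_invariance(self, rng):
        r = rng.uniform(10, 100, size=6)
        t = rng.uniform(10, 100, size=6)
        perm = rng.permutation(6)
        assert fit_factor_f1(r, t) == pytest.approx(fit_factor_f1(r[perm], t[perm]))
        assert fit_factor_f2(r, t) == pytest.approx(fit_factor_f2(r[perm], t[perm]))

    def test_swap_asymmetry_f1_symmetry_f2(self):
        r, t = [88.0, 100.0], [60.0, 67.0]
        assert fit_factor_f1(r, t) != pytest.approx(fit_factor_f1(t, r))
        assert fit_factor_f2(r, t) == pytest.approx(fit_factor_f2(t, r))

    def test_guidance_mode_truncates_after_85_percent(self):
        r = [40.0, 70.0, 90.0, 98.0, 99.0]
        t = [35.0, 60.0, 85.0, 97.0, 99.0]
        ff = compute_fit_factors(r, t, point_times=[15, 30, 45, 60, 90], until_reference_pct=85.0)
        assert ff.n_points == 3
        assert ff.point_times == (15.0, 30.0, 45.0)


class TestVerdict:
    @pytest.mark.parametrize(
        "f1, f2, expected",
        [
            (0.88, 85.67, Verdict.SIMILAR),  # HPLC-mode published pair
            (16.18, 63.0, Verdict.NOT_SIMILAR),  # UV-mode pair fails f1 <= 15
            (0.0, 100.0, Verdict.SIMILAR),
        ],
    )
    def test_default_thresholds(self, f1, f2, expected):
        assert similarity_verdict(FitFactors(f1=f1, f2=f2, n_points=4)) is expected

    def test_configurable_thresholds(self):
        ff = FitFactors(f1=16.18, f2=63.0, n_points=4)
        assert similarity_verdict(ff, f1_max=20.0) is Verdict.SIMILAR


def make_profile(times, values, fid="F", mode="UV"):
    return DissolutionProfile(fid, mode, "r1", np.asarray(times, float), np.asarray(values, float))


class TestReleaseRate:
    def test_brand_like_rate(self):
        p = make_profile([25, 50, 75], [80, 100, 100])
        assert release_rate(p, dose_ug=1500) == pytest.approx(30.0)

    def test_generic_like_rate(self):
        p = make_profile([50, 100, 150], [70, 100, 100])
        assert release_rate(p, dose_ug=1500) == pytest.approx(15.0)

    def test_flat_profile_uses_first_point(self):
        p = make_profile([10, 20, 30], [100, 100, 100])
        assert release_rate(p, dose_ug=1500) == pytest.approx(150.0)

    def test_plateau_never_reached(self):
        p = make_profile([10, 20, 30], [40, 60, 70])
        with pytest.raises(ValueError, match="not at plateau"):
            release_rate(p, dose_ug=1500)


class TestProfileInvariants:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            make_profile([10, 10, 20], [1, 2, 3])

    def test_values_bounded(self):
        with pytest.raises(ValueError):
            make_profile([10, 20], [50, 130])
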