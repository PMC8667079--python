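"""The tanh Fourier low-pass, circular peak counting, detection-rate search."""

import numpy as np
import pytest

from sliscat.profiles import SLIProfile
from sliscat.smoothing import (
    PRESETS,
    DetectionGrid,
    FilterParams,
    SmoothingError,
    circular_peaks,
    count_significant_peaks,
    detection_rate,
    filter_gain,
    lowpass,
    lowpass_values,
    optimize_filter,
)
from sliscat.synthetic import region_fixture


def profile_1deg(values):
    return SLIProfile(values=np.asarray(values, dtype=float), delta_phi=1.0)


def tanh_gain(g, cutoff, width):
    # closed-form reference, written independently of the implementation
    return 1.0 - (0.5 + 0.5 * np.tanh((g - cutoff) / width))


class TestLowpass:
    @pytest.mark.parametrize("preset", ["sli-1deg", "sli-5deg"])
    def test_dc_gain_matches_closed_form(self, preset):
        params = PRESETS[preset]
        constant = profile_1deg(np.full(360, 3.7))
        out = lowpass(constant, params)
        expected = 3.7 * tanh_gain(0.0, params.cutoff, params.width)
        assert np.allclose(out.values, expected, atol=1e-9)

    @pytest.mark.parametrize("preset", ["sli-1deg", "sli-5deg"])
    def test_nyquist_gain_matches_closed_form(self, preset):
        params = PRESETS[preset]
        alternating = profile_1deg(np.tile([1.0, -1.0], 180))
        out = lowpass(alternating, params)
        expected = tanh_gain(1.0, params.cutoff, params.width)
        assert np.allclose(out.values / alternating.values, expected, atol=1e-9)

    def test_filter_is_zero_phase(self):
        # profile symmetric about phi0 stays symmetric about phi0
        phi = np.arange(360)
        values = np.exp(-((np.minimum(np.abs(phi - 77), 360 - np.abs(phi - 77))) ** 2) / 500)
        out = lowpass_values(values, PRESETS["sli-1deg"])
        reflected = np.roll(out[::-1], 2 * 77 + 1)
        assert np.allclose(out, reflected, atol=1e-9)

    def test_linearity(self, rng):
        p = rng.uniform(size=360)
        q = rng.uniform(size=360)
        params = PRESETS["sli-1deg"]
        lhs = lowpass_values(2.0 * p + 3.0 * q, params)
        rhs = 2.0 * lowpass_values(p, params) + 3.0 * lowpass_values(q, params)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_shift_equivariance(self, rng):
        values = rng.uniform(size=360)
        params = PRESETS["sli-1deg"]
        shifted = lowpass_values(np.roll(values, 45), params)
        assert np.allclose(np.roll(shifted, -45), lowpass_values(values, params),
                           atol=1e-9)

    def test_length_and_step_preserved(self, rng):
        profile = SLIProfile(values=rng.uniform(size=72), delta_phi=5.0,
                             radius_px=17)
        out = lowpass(profile, PRESETS["sli-5deg"])
        assert len(out) == 72 and out.delta_phi == 5.0 and out.radius_px == 17

    def test_zero_width_rejected(self):
        with pytest.raises(SmoothingError):
            FilterParams(cutoff=0.1, width=0.0)

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(SmoothingError):
            FilterParams(cutoff=0.0, width=0.1)
        with pytest.raises(SmoothingError):
            FilterParams(cutoff=0.5, width=0.3)

    def test_gain_decreases_with_frequency(self):
        g = np.linspace(0, 1, 50)
        gains = filter_gain(g, PRESETS["sli-1deg"])
        assert np.all(np.diff(gains) < 0)


def oracle_circular_peak_count(values, prominence_threshold):
    """Exhaustive circular scan with an explicit prominence walk."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return 0
    norm = (values - lo) / (hi - lo)
    n = len(norm)
    # rotate so a global minimum sits at index 0 (never a peak)
    start = int(np.argmin(norm))
    rolled = np.roll(norm, -start)
    count = 0
    i = 1
    while i < n:
        j = i
        while j + 1 < n and rolled[j + 1] == rolled[i]:
            j += 1  # plateau
        left = rolled[i - 1]
        right = rolled[(j + 1) % n]
        if left < rolled[i] and right < rolled[i]:
            # walk both ways to the nearest strictly higher ground
            height = rolled[i]
            def walk(direction, edge):
                low = height
                k = edge
                for _ in range(n):
                    k = (k + direction) % n
                    if rolled[k] > height:
                        break
                    low = min(low, rolled[k])
                return low
            prominence = height - max(walk(-1, i), walk(+1, j))
            if prominence >= prominence_threshold:
                count += 1
        i = j + 1
    return count


class TestPeakCounting:
    def test_two_peaks_per_sine_squared_period(self):
        phi = np.radians(np.arange(360))
        assert count_significant_peaks(profile_1deg(np.sin(phi) ** 2)) == 2

    def test_four_peaks_for_doubled_frequency(self):
        phi = np.radians(np.arange(360))
        assert count_significant_peaks(profile_1deg(np.sin(2 * phi) ** 2)) == 4

    def test_flat_profile_has_no_peaks(self):
        assert count_significant_peaks(profile_1deg(np.full(360, 2.0))) == 0

    def test_plateau_counts_once_at_midpoint(self):
        values = np.zeros(72)
        values[10:15] = 1.0
        idx, _ = circular_peaks(values, 0.5)
        assert list(idx) == [12]

    def test_plateau_across_the_wrap_seam(self):
        values = np.zeros(72)
        values[70:] = 1.0
        values[:3] = 1.0
        idx, _ = circular_peaks(values, 0.5)
        assert len(idx) == 1

    def test_matches_exhaustive_circular_oracle(self, rng):
        phi = np.radians(np.arange(360))
        for _ in range(500):
            k1, k2 = rng.integers(1, 6, size=2)
            values = (
                rng.uniform(0.5, 2.0) * np.sin(k1 * phi + rng.uniform(0, 7)) ** 2
                + rng.uniform(0.2, 1.0) * np.sin(k2 * phi + rng.uniform(0, 7)) ** 2
                + rng.normal(0, 0.15, size=360)
            )
            assert count_significant_peaks(profile_1deg(values), 0.08) == (
                oracle_circular_peak_count(values, 0.08)
            )


class TestDetectionRate:
    @pytest.fixture
    def crossing2_noiseless(self):
        return region_fixture("crossing2", 40, seed=21, noise=None)

    def test_noiseless_crossing2_fully_detected(self, crossing2_noiseless):
        profiles, accepted = crossing2_noiseless
        assert accepted == {4}
        assert detection_rate(profiles, accepted) == 1.0

    def test_wrong_expected_count_detects_nothing(self, crossing2_noiseless):
        profiles, _ = crossing2_noiseless
        assert detection_rate(profiles, {6}) == 0.0

    def test_rate_equals_manual_tally(self):
        from sliscat.orientation import pair_peaks

        profiles, accepted = region_fixture("crossing2", 50, seed=33)
        params = PRESETS["sli-1deg"]
        rate = detection_rate(profiles, accepted, params)
        hits = 0
        for profile in profiles:
            smoothed = lowpass(profile, params)
            idx, _ = circular_peaks(smoothed.values, 0.08)
            if len(idx) in accepted:
                _, unpaired = pair_peaks(idx * profile.delta_phi)
                if not unpaired:
                    hits += 1
        assert rate == pytest.approx(hits / len(profiles))

    def test_empty_inputs_rejected(self):
        profiles, _ = region_fixture("crossing2", 2, seed=1, noise=None)
        with pytest.raises(SmoothingError):
            detection_rate(profiles, set())
        with pytest.raises(SmoothingError):
            detection_rate([], {4})


class TestOptimizeFilter:
    def _fixture_profiles(self, values_list):
        return [profile_1deg(v) for v in values_list]

    def test_single_region_unique_best_cell(self):
        profiles, accepted = region_fixture("parallel_inplane", 30, seed=8)
        params, grid = optimize_filter(
            {"region": (profiles, accepted)},
            cutoffs=[0.04, 0.2],
            widths=[0.125, 0.25],
        )
        matrix = grid.rates["region"]
        best = np.unravel_index(np.argmax(matrix), matrix.shape)
        assert params.cutoff == grid.cutoffs[best[0]]
        assert params.width == grid.widths[best[1]]

    def test_tie_breaks_to_lowest_cutoff_then_width(self):
        grid = DetectionGrid(
            cutoffs=np.array([0.1, 0.2]),
            widths=np.array([0.05, 0.1]),
            rates={"a": np.array([[0.5, 1.0], [1.0, 0.5]]),
                   "b": np.array([[0.5, 1.0], [1.0, 0.5]])},
        )
        total = grid.summed_normalized()
        best = np.unravel_index(np.argmax(total), total.shape)
        assert (best[0], best[1]) == (0, 1)  # lowest cutoff wins the tie

    def test_all_zero_region_excluded_with_warning(self):
        profiles, _ = region_fixture("parallel_inplane", 10, seed=9)
        with pytest.warns(UserWarning, match="excluded"):
            params, grid = optimize_filter(
                {
                    "good": (profiles, {2}),
                    "impossible": (profiles, {11}),
                },
                cutoffs=[0.04, 0.2],
                widths=[0.125],
            )
        assert grid.rates["impossible"].max() == 0

    def test_argmax_reproducible_from_emitted_grid(self, tmp_path):
        suite = {
            kind: region_fixture(kind, 25, seed=40 + k)
            for k, kind in enumerate(["parallel_inplane", "crossing2"])
        }
        cutoffs = [0.02, 0.04, 0.1, 0.3]
        widths = [0.075, 0.125, 0.2]
        params, grid = optimize_filter(suite, cutoffs=cutoffs, widths=widths)
        csv_path = tmp_path / "grid.csv"
        grid.write_csv(csv_path)
        # recompute the argmax of summed normalised matrices from the CSV
        rows = np.genfromtxt(
            csv_path, delimiter=",", names=True, dtype=None, encoding="utf-8"
        )
        total = np.zeros((len(cutoffs), len(widths)))
        for region in set(rows["region"]):
            sel = rows[rows["region"] == region]
            matrix = np.zeros_like(total)
            for entry in sel:
                i = cutoffs.index(float(entry["cutoff"]))
                j = widths.index(float(entry["width"]))
                matrix[i, j] = entry["rate"]
            if matrix.max() > 0:
                total += matrix / matrix.max()
        best = np.unravel_index(np.argmax(total), total.shape)
        assert params.cutoff == pytest.approx(cutoffs[best[0]])
        assert params.width == pytest.approx(widths[best[1]])

    def test_no_regions_rejected(self):
        with pytest.raises(SmoothingError):
            optimize_filter({})
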