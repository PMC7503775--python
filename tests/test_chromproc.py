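"""Preprocessing chain: normalization, differentiation, COW, detection."""

from itertools import product

import numpy as np
import pytest

from phenolome import simdata
from phenolome.chromproc import (
    build_common_peaks,
    cow_align,
    detect_peaks,
    integrate_peaks,
    merge_wavelengths,
    normalize_by_mass,
    remove_baseline_by_differentiation,
    run_preprocessing,
    smooth_second_derivative,
)
from phenolome.config import PipelineConfig
from phenolome.containers import Chromatogram, PeakInterval

import pandas as pd


def chrom(intensity, mass=1.0, rt=None):
    intensity = np.asarray(intensity, dtype=float)
    rt = np.arange(intensity.size, dtype=float) if rt is None else rt
    return Chromatogram(rt, intensity, 280, "s1", mass)


class TestNormalize:
    def test_divides_by_mass(self):
        out = normalize_by_mass(chrom([2.0, 4.0], mass=100.0))
        np.testing.assert_allclose(out.intensity, [0.02, 0.04])

    def test_mass_one_is_identity_and_idempotent(self):
        c = chrom([1.0, 2.0, 3.0], mass=1.0)
        out = normalize_by_mass(normalize_by_mass(c))
        np.testing.assert_array_equal(out.intensity, c.intensity)

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            Chromatogram(np.arange(3.0), np.zeros(3), 280, "s", 0.0)


class TestDifferentiation:
    def test_constant_maps_to_zero(self):
        d = remove_baseline_by_differentiation(chrom(np.full(50, 7.0)))
        np.testing.assert_allclose(d, 0.0, atol=1e-14)

    def test_linear_maps_to_constant_slope(self):
        d = remove_baseline_by_differentiation(chrom(3.0 * np.arange(50.0)))
        np.testing.assert_allclose(d, 3.0)

    def test_gaussian_on_linear_baseline_zero_crossing_at_apex(self):
        n = 400
        t = np.arange(n, dtype=float)
        b = 0.01
        y = np.exp(-0.5 * ((t - 200) / 10.0) ** 2) + b * t + 5.0
        d = remove_baseline_by_differentiation(chrom(y)) - b
        sign_change = np.flatnonzero(np.diff(np.sign(d[150:250]))) + 150
        assert any(abs(i - 200) <= 1 for i in sign_change)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            remove_baseline_by_differentiation(chrom([1.0, 2.0]))


def _brute_force_cow_score(sig, ref, seg_len, slack):
    """Exhaustive enumeration over all node-shift vectors."""
    n = len(sig)
    n_seg = max(1, round((n - 1) / seg_len))
    bounds = np.round(np.linspace(0, n - 1, n_seg + 1)).astype(int)
    best = -np.inf
    for us in product(range(-slack, slack + 1), repeat=n_seg - 1):
        xs = [0] + [bounds[i + 1] + us[i] for i in range(n_seg - 1)] + [n - 1]
        if any(xs[i + 1] - xs[i] < 1 for i in range(n_seg)):
            continue
        if any(x < 1 or x > n - 2 for x in xs[1:-1]):
            continue
        total = 0.0
        for i in range(n_seg):
            rseg = ref[bounds[i] : bounds[i + 1] + 1]
            v = np.interp(np.linspace(xs[i], xs[i + 1], rseg.size), np.arange(n), sig)
            if v.std() == 0 or rseg.std() == 0:
                continue
            total += np.corrcoef(v, rseg)[0, 1]
        best = max(best, total)
    return best


class TestCow:
    def test_identity_when_signal_equals_reference(self):
        rng = np.random.default_rng(0)
        t = np.arange(300.0)
        ref = np.exp(-0.5 * ((t - 150) / 8) ** 2) + 0.01 * rng.normal(size=300)
        res = cow_align(ref, ref, segment_len=50, slack=4)
        n_seg = len(res.ref_nodes) - 1
        np.testing.assert_array_equal(res.shifts, 0)
        np.testing.assert_allclose(res.score, n_seg, atol=1e-9)
        np.testing.assert_allclose(res.warped, ref, atol=1e-12)

    def test_slack_zero_is_identity(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=200)
        ref = rng.normal(size=200)
        res = cow_align(sig, ref, segment_len=40, slack=0)
        np.testing.assert_allclose(res.warped, sig, atol=1e-12)

    def test_recovers_planted_uniform_shift(self):
        n = 400
        t = np.arange(n)
        ref = sum(np.exp(-0.5 * ((t - c) / 6.0) ** 2) for c in [60, 140, 220, 300, 360])
        sig = np.interp(t - 3, t, ref)
        res = cow_align(sig, ref, segment_len=50, slack=5)
        interior = res.shifts[1:-1]
        assert np.all(np.abs(interior - 3) <= 1)
        assert np.corrcoef(res.warped, ref)[0, 1] >= 0.99

    @pytest.mark.parametrize("seed", range(6))
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        t = np.arange(n)
        ref = sum(
            np.exp(-0.5 * ((t - c) / 4.0) ** 2) for c in [20, 50, 80, 105]
        ) + 0.05 * rng.normal(size=n)
        shift = int(rng.integers(-2, 3))
        sig = np.interp(t - shift, t, ref) + 0.05 * rng.normal(size=n)
        res = cow_align(sig, ref, segment_len=25, slack=3)
        brute = _brute_force_cow_score(sig, ref, 25, 3)
        np.testing.assert_allclose(res.score, brute, atol=1e-9)

    def test_warp_monotone_and_endpoint_fixed(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=250)
        ref = rng.normal(size=250)
        res = cow_align(sig, ref, segment_len=25, slack=6)
        assert np.all(np.diff(res.signal_nodes) >= 1)
        assert res.signal_nodes[0] == 0 and res.signal_nodes[-1] == 249

    def test_never_worse_than_identity_warp(self):
        rng = np.random.default_rng(8)
        t = np.arange(300)
        ref = np.exp(-0.5 * ((t - 100) / 5.0) ** 2)
        sig = np.interp(t - 4, t, ref) + 0.02 * rng.normal(size=300)
        opt = cow_align(sig, ref, segment_len=30, slack=6).score
        identity = cow_align(sig, ref, segment_len=30, slack=0).score
        assert opt >= identity - 1e-12

    def test_invalid_parameters(self):
        sig = np.zeros(100)
        with pytest.raises(ValueError):
            cow_align(sig, sig, segment_len=10, slack=10)
        with pytest.raises(ValueError):
            cow_align(sig, np.zeros(99), 10, 2)
        with pytest.raises(ValueError):
            cow_align(sig, sig, segment_len=1, slack=0)


class TestSmoothSecondDerivative:
    def test_quadratic_gives_constant_second_derivative(self):
        n = 1000
        t = np.arange(n, dtype=float)
        a = 3e-4
        first = remove_baseline_by_differentiation(chrom(a * t**2))
        d2 = smooth_second_derivative(first, n_knots=100)
        interior = d2[50:-50]
        np.testing.assert_allclose(interior, 2 * a, rtol=1e-3)

    def test_gaussian_minimum_at_apex(self):
        n = 1200
        t = np.arange(n, dtype=float)
        y = np.exp(-0.5 * ((t - 600) / 30.0) ** 2)
        d2 = smooth_second_derivative(np.gradient(y), n_knots=200)
        assert abs(int(np.argmin(d2)) - 600) <= 2

    def test_roughness_grows_with_knots_under_noise(self):
        rng = np.random.default_rng(5)
        n = 1000
        t = np.arange(n, dtype=float)
        y = np.gradient(np.exp(-0.5 * ((t - 500) / 40.0) ** 2)) + 0.001 * rng.normal(
            size=n
        )
        rough = []
        for k in (50, 100, 520):
            d2 = smooth_second_derivative(y, n_knots=k)
            rough.append(float(np.sum(np.diff(d2, 2) ** 2)))
        assert rough[0] <= rough[1] <= rough[2]

    def test_too_many_knots_rejected(self):
        with pytest.raises(ValueError):
            smooth_second_derivative(np.zeros(100), n_knots=100)


class TestDetectPeaks:
    def test_flat_profile_yields_nothing(self):
        assert detect_peaks(np.zeros(100), np.zeros(100)) == []

    def test_single_gaussian_one_interval_containing_apex(self):
        n = 1200
        t = np.arange(n, dtype=float)
        y = 0.5 * np.exp(-0.5 * ((t - 600) / 30.0) ** 2)
        first = np.gradient(y)
        d2 = smooth_second_derivative(first, n_knots=200)
        peaks = detect_peaks(d2, first, intensity_tolerance=0.0005)
        assert len(peaks) == 1
        assert peaks[0].start_idx <= 600 < peaks[0].end_idx

    def test_subtolerance_peak_discarded(self):
        n = 1200
        t = np.arange(n, dtype=float)
        y = np.exp(-0.5 * ((t - 600) / 30.0) ** 2)
        first = np.gradient(y)
        first *= 0.0004 / np.abs(first).max()  # max |derivative| just below 0.0005
        d2 = smooth_second_derivative(first, n_knots=200)
        assert detect_peaks(d2, first, intensity_tolerance=0.0005) == []

    def test_intervals_disjoint_and_min_length_two(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=800)
        d2 = smooth_second_derivative(sig, n_knots=150)
        peaks = detect_peaks(d2, sig, intensity_tolerance=0.0)
        for p in peaks:
            assert len(p) >= 2
        for a, b in zip(peaks, peaks[1:]):
            assert a.end_idx <= b.start_idx


class TestCommonPeaks:
    def test_identical_intervals_merge_with_support(self):
        ivs = {
            "s1": [PeakInterval(10, 20, 15)],
            "s2": [PeakInterval(10, 20, 15)],
        }
        out = build_common_peaks(ivs, c1=2)
        assert len(out) == 1
        assert out[0].interval.start_idx == 10 and out[0].interval.end_idx == 20
        assert out[0].support == 2

    def test_overlap_union(self):
        ivs = {
            "s1": [PeakInterval(10, 20, 12)],
            "s2": [PeakInterval(15, 25, 18)],
        }
        out = build_common_peaks(ivs, c1=1)
        assert len(out) == 1
        assert (out[0].interval.start_idx, out[0].interval.end_idx) == (10, 25)

    def test_low_support_dropped(self):
        ivs = {
            "s1": [PeakInterval(10, 20, 12)],
            "s2": [],
            "s3": [],
        }
        assert build_common_peaks(ivs, c1=2) == []

    def test_adjacent_halfopen_intervals_not_merged(self):
        ivs = {"s1": [PeakInterval(10, 15, 12)], "s2": [PeakInterval(15, 20, 17)]}
        out = build_common_peaks(ivs, c1=1)
        assert len(out) == 2

    def test_permutation_invariance_and_idempotence(self):
        rng = np.random.default_rng(2)
        samples = {}
        for s in range(5):
            start = np.sort(rng.choice(np.arange(0, 400, 7), 10, replace=False))
            samples[f"s{s}"] = [
                PeakInterval(int(a), int(a + rng.integers(3, 9)), int(a + 1))
                for a in start
            ]
        out1 = build_common_peaks(samples, c1=2)
        reordered = dict(reversed(list(samples.items())))
        out2 = build_common_peaks(reordered, c1=2)
        assert [(c.interval, c.support) for c in out1] == [
            (c.interval, c.support) for c in out2
        ]
        again = build_common_peaks({"all": [c.interval for c in out1]}, c1=1)
        assert [c.interval for c in again] == [c.interval for c in out1]

    def test_c1_above_sample_count_warns_and_empties(self):
        with pytest.warns(UserWarning):
            out = build_common_peaks({"s1": [PeakInterval(0, 5, 2)]}, c1=2)
        assert out == []


class TestIntegratePeaks:
    def test_zero_signal_integrates_to_zero(self):
        peaks = build_common_peaks({"s": [PeakInterval(5, 15, 9)]}, c1=1)
        table = integrate_peaks({"s": np.zeros(50)}, peaks)
        assert (table.to_numpy() == 0).all()

    def test_unit_rectangle_has_area_equal_width(self):
        sig = np.zeros(100)
        sig[20:41] = 1.0  # 20 index steps of 0.03 min each
        peaks = build_common_peaks({"s": [PeakInterval(20, 41, 30)]}, c1=1)
        table = integrate_peaks({"s": sig}, peaks, dx=0.03)
        np.testing.assert_allclose(table.iloc[0, 0], 0.6, rtol=1e-12)

    def test_gaussian_rectified_derivative_integral_is_peak_height(self):
        n = 2000
        t = np.arange(n, dtype=float)
        amp = 0.7
        y = amp * np.exp(-0.5 * ((t - 1000) / 40.0) ** 2)
        first = np.gradient(y)
        peaks = build_common_peaks({"s": [PeakInterval(800, 1200, 1000)]}, c1=1)
        table = integrate_peaks({"s": first}, peaks)
        np.testing.assert_allclose(table.iloc[0, 0], amp, rtol=0.01)

    def test_interval_outside_grid_rejected(self):
        peaks = build_common_peaks({"s": [PeakInterval(5, 200, 9)]}, c1=1)
        with pytest.raises(IndexError):
            integrate_peaks({"s": np.zeros(50)}, peaks)


class TestMergeWavelengths:
    def _tables(self):
        idx = ["s1", "s2"]
        a = pd.DataFrame({"P001": [3.0, 1.0], "P002": [2.0, 2.0]}, index=idx)
        b = pd.DataFrame({"P001": [5.0, 1.0]}, index=idx)
        return a, b

    def test_same_name_summed_across_wavelengths(self):
        a, b = self._tables()
        merged = merge_wavelengths(a, b, {"a:P001": ["lutonarin"], "b:P001": ["lutonarin"]})
        np.testing.assert_allclose(merged.loc["s1", "lutonarin"], 8.0)
        assert merged.shape[1] == 2

    def test_no_shared_names_concatenates(self):
        a, b = self._tables()
        merged = merge_wavelengths(a, b, {})
        assert merged.shape == (2, 3)
        np.testing.assert_allclose(merged.loc["s1", "a:P001"], 3.0)

    def test_coeluting_names_keep_multi_label(self):
        a, b = self._tables()
        merged = merge_wavelengths(a, b, {"a:P002": ["tricin", "tricin-glc"]})
        assert "tricin;tricin-glc" in merged.columns

    def test_duplicate_name_within_wavelength_rejected(self):
        a, b = self._tables()
        with pytest.raises(ValueError):
            merge_wavelengths(a, b, {"a:P001": ["x"], "a:P002": ["x"]})

    def test_sample_set_mismatch_rejected(self):
        a, b = self._tables()
        with pytest.raises(ValueError):
            merge_wavelengths(a, b.iloc[:1], {})


class TestRunPreprocessing:
    def _noisefree(self, small_design, warp):
        cs, truth = simdata.simulate_experiment(
            small_design,
            n_metabolites=12,
            category_assignment=["NoEffect"] * 12,
            noise_sd=0.0,
            warp_magnitude=warp,
            seed=0,
        )
        cfg = PipelineConfig(seed=0, c1=len(small_design))
        return cs, truth, run_preprocessing(cfg, cs)

    def test_exact_recovery_without_noise_or_warp(self, small_design):
        _, _, res = self._noisefree(small_design, warp=0.0)
        assert res.counts["variables"] == 12

    def test_recovery_with_warp_within_slack(self, small_design):
        cs, truth, res = self._noisefree(small_design, warp=0.05)
        assert res.counts["variables"] == 12
        rt = cs.chromatograms[0].rt
        step = rt[1] - rt[0]
        apexes = np.sort([rt[c.interval.apex_idx] for c in res.common_peaks[280]])
        planted = np.sort(list(truth.apex_rt.values()))
        assert np.max(np.abs(apexes - planted)) <= 2 * step + 1e-12

    def test_normalization_equivariance(self, small_design):
        cs, _, res = self._noisefree(small_design, warp=0.0)
        # a power-of-two factor keeps the mass division bit-exact, so the
        # scaled set must preprocess to the identical metabolite table
        scaled = [
            Chromatogram(c.rt, c.intensity * 8.0, c.wavelength, c.sample_id,
                         c.sample_mass * 8.0)
            for c in cs
        ]
        from phenolome.containers import ChromatogramSet

        cs2 = ChromatogramSet(scaled, cs.design)
        res2 = run_preprocessing(PipelineConfig(seed=0, c1=len(cs.design)), cs2)
        vars1 = res.table[[c for c in res.table.columns if c.startswith("RT")]]
        vars2 = res2.table[[c for c in res2.table.columns if c.startswith("RT")]]
        pd.testing.assert_frame_equal(vars1, vars2)

    def test_empty_set_rejected(self):
        from phenolome.containers import ChromatogramSet

        with pytest.raises(ValueError):
            run_preprocessing(PipelineConfig(), ChromatogramSet([], pd.DataFrame()))
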