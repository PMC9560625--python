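"""Smoothing, baseline correction, peak picking and deisotoping."""

import numpy as np
import pytest

from zooms_screen.preprocess import (
    Peak,
    PeakList,
    PreprocessConfig,
    correct_baseline,
    deisotope,
    estimate_noise,
    pick_peaks,
    process_spectrum,
    read_peaklist_csv,
    smooth,
    write_peaklist_csv,
)
from zooms_screen.spectra_io import ParameterError, Spectrum

CFG = PreprocessConfig()


def uniform_spectrum(intensity, lo=1000.0, step=0.02, **kw):
    intensity = np.asarray(intensity, float)
    mz = lo + step * np.arange(intensity.size)
    kw.setdefault("mz_range", (lo, float(mz[-1])))
    return Spectrum(mz, intensity, **kw)


def gaussian(grid, centre, apex, sigma=0.08):
    return apex * np.exp(-0.5 * ((grid - centre) / sigma) ** 2)


class TestSmooth:
    def test_constant_unchanged(self):
        s = uniform_spectrum(np.full(1000, 7.0))
        out = smooth(s, CFG)
        assert np.allclose(out.intensity, 7.0)

    def test_fractional_cycles_is_convex_blend(self):
        rng = np.random.default_rng(0)
        s = uniform_spectrum(rng.uniform(5, 10, 2000))
        y1 = smooth(s, PreprocessConfig(smooth_cycles=1)).intensity
        y2 = smooth(s, PreprocessConfig(smooth_cycles=2)).intensity
        y15 = smooth(s, PreprocessConfig(smooth_cycles=1.5)).intensity
        assert np.allclose(y15, 0.5 * (y1 + y2))
        # the blend sits exactly midway between the 1- and 2-pass outputs
        assert np.linalg.norm(y15 - y1) == pytest.approx(np.linalg.norm(y15 - y2))
        assert np.linalg.norm(y15 - y1) == pytest.approx(
            0.5 * np.linalg.norm(y2 - y1)
        )

    def test_spike_mass_conserved(self):
        y = np.full(2000, 1.0)
        y[1000] = 100.0
        s = uniform_spectrum(y)
        out = smooth(s, CFG)
        assert out.intensity[1000] < 100.0
        assert abs(out.intensity.sum() - y.sum()) / y.sum() < 0.01

    def test_requires_uniform_grid(self):
        s = Spectrum(np.array([1000.0, 1000.1, 1001.0]), np.ones(3),
                     mz_range=(1000.0, 1001.0))
        with pytest.raises(ParameterError):
            smooth(s, CFG)


class TestBaseline:
    def test_flat_offset_removed_exactly(self):
        s = uniform_spectrum(np.full(5000, 4.2))
        out, baseline = correct_baseline(s, CFG)
        assert np.allclose(out.intensity, 0.0)
        assert np.allclose(baseline, 4.2)

    def test_ramp_plus_peak_apex_recovered(self):
        grid = 1000.0 + 0.02 * np.arange(20000)
        ramp = 0.01 * (grid - grid[0])
        peak = gaussian(grid, 1200.0, 50.0)
        s = Spectrum(grid, ramp + peak, mz_range=(1000.0, float(grid[-1])))
        out, _ = correct_baseline(s, CFG)
        apex = out.intensity[np.argmin(np.abs(grid - 1200.0))]
        assert abs(apex - 50.0) / 50.0 < 0.05

    def test_zero_offset_anchors_are_window_minima(self):
        rng = np.random.default_rng(1)
        s = uniform_spectrum(rng.uniform(1, 5, 4000))
        out, baseline = correct_baseline(s, CFG)
        # with offset 0 the baseline passes through each window's minimum,
        # so every window of the corrected spectrum touches zero
        bounds = np.linspace(0, s.n_points, CFG.baseline_segments + 1).astype(int)
        for i in range(CFG.baseline_segments):
            assert out.intensity[bounds[i]:bounds[i + 1]].min() == pytest.approx(0.0)

    def test_too_few_points_rejected(self):
        s = uniform_spectrum(np.ones(50))
        with pytest.raises(ParameterError):
            correct_baseline(s, CFG)


class TestPickPeaks:
    def test_flat_zero_gives_empty_list(self):
        s = uniform_spectrum(np.zeros(1000), lo=1000.0)
        assert len(pick_peaks(s, CFG)) == 0

    def test_single_gaussian_centroid_accuracy(self):
        grid = 1050.0 + 0.02 * np.arange(10000)
        y = gaussian(grid, 1105.60, 20.0)
        s = Spectrum(grid, y, mz_range=(1050.0, float(grid[-1])))
        pl = pick_peaks(s, CFG, noise=1.0)
        assert len(pl) == 1
        assert abs(pl.peaks[0].mz - 1105.60) <= 0.02
        assert pl.peaks[0].sn == pytest.approx(20.0)

    @pytest.mark.parametrize("apex,expected", [(3.4, 0), (3.6, 1)])
    def test_sn_threshold_boundary(self, apex, expected):
        grid = 1050.0 + 0.02 * np.arange(5000)
        y = gaussian(grid, 1100.0, apex)
        s = Spectrum(grid, y, mz_range=(1050.0, float(grid[-1])))
        assert len(pick_peaks(s, CFG, noise=1.0)) == expected

    def test_relative_intensity_floor(self):
        grid = 1050.0 + 0.02 * np.arange(10000)
        y = gaussian(grid, 1100.0, 1000.0) + gaussian(grid, 1150.0, 4.0)
        s = Spectrum(grid, y, mz_range=(1050.0, float(grid[-1])))
        # 4.0 has S/N 4 > 3.5 but is below 0.5% of the 1000 base peak
        pl = pick_peaks(s, CFG, noise=1.0)
        assert len(pl) == 1
        assert abs(pl.peaks[0].mz - 1100.0) < 0.1


def peak(mz, intensity=10.0, sn=10.0):
    return Peak(mz=mz, intensity=intensity, sn=sn)


class TestDeisotope:
    def test_single_envelope_collapses(self):
        pl = PeakList("s", [peak(1105.6, 30), peak(1106.6, 20), peak(1107.6, 8)], 30)
        out = deisotope(pl, CFG)
        assert len(out) == 1
        head = out.peaks[0]
        assert head.mz == 1105.6
        assert head.is_monoisotopic
        assert len(head.envelope) == 3

    def test_two_envelopes_2p5_th_apart_separate(self):
        mzs_a = [1000.0, 1001.00235, 1002.0047]
        mzs_b = [1002.5, 1003.50235, 1004.5047]
        peaks = [peak(m, i) for m, i in zip(mzs_a, [30, 20, 8])]
        peaks += [peak(m, i) for m, i in zip(mzs_b, [25, 16, 6])]
        out = deisotope(PeakList("s", peaks, 30), CFG)
        assert len(out) == 2
        assert [round(p.mz, 1) for p in out.peaks] == [1000.0, 1002.5]
        assert all(len(p.envelope) == 3 for p in out.peaks)

    def test_singleton_passes_through(self):
        out = deisotope(PeakList("s", [peak(1500.0)], 10), CFG)
        assert len(out) == 1
        assert len(out.peaks[0].envelope) == 1

    def test_rising_tail_after_third_isotope_splits(self):
        # decreasing triplet followed by a *stronger* peak one spacing up:
        # the riser must start a new cluster, not extend the old one
        mz0 = 2000.0
        peaks = [
            peak(mz0, 30), peak(mz0 + 1.00235, 20), peak(mz0 + 2 * 1.00235, 8),
            peak(mz0 + 3 * 1.00235, 28),
        ]
        out = deisotope(PeakList("s", peaks, 30), CFG)
        assert len(out) == 2
        assert len(out.peaks[0].envelope) == 3

    def test_well_separated_envelopes_match_construction(self, rng):
        # construction oracle: n envelopes at >=3 Th spacing must come back
        # as exactly n monoisotopic peaks with the constructed sizes
        n_env = 8
        monos = np.cumsum(rng.uniform(3.0, 8.0, n_env)) + 900.0
        sizes = rng.integers(1, 5, n_env)
        peaks = []
        for mono, size in zip(monos, sizes):
            for j in range(size):
                peaks.append(peak(mono + j * 1.00235, 30.0 / (j + 1)))
        out = deisotope(PeakList("s", peaks, 30), CFG)
        assert len(out) == n_env
        assert np.allclose([p.mz for p in out.peaks], monos)
        assert [len(p.envelope) for p in out.peaks] == list(sizes)

    def test_monotone_reduction(self, rng):
        mzs = np.sort(rng.uniform(1000, 1100, 40))
        mzs = mzs[np.concatenate([[True], np.diff(mzs) > 0.01])]
        pl = PeakList("s", [peak(m, rng.uniform(1, 30)) for m in mzs], 30)
        assert len(deisotope(pl, CFG)) <= len(pl)


class TestChain:
    def _marker_spectrum(self, seed, apexes={1105.6: 12.0, 1192.5: 15.0}):
        rng = np.random.default_rng(seed)
        lo, hi, step = 1050.0, 1260.0, 0.02
        grid = lo + step * np.arange(int((hi - lo) / step) + 1)
        y = np.zeros_like(grid)
        for mono, apex in apexes.items():
            for j, frac in enumerate([1.0, 0.6, 0.2]):
                y += gaussian(grid, mono + j * 1.00235, apex * frac)
        y += 3.0 * (1 - (grid - lo) / (hi - lo))  # drifting baseline
        y = np.clip(y + rng.normal(0, 1.0, grid.size), 0, None)
        return Spectrum(grid, y, mz_range=(lo, hi))

    def test_marker_recovery_rate(self):
        """Markers of S/N >= 10 are recovered within 0.05 Th in >=99% of trials."""
        truths = [1105.6, 1192.5]
        n_trials, hits = 100, 0
        for seed in range(n_trials):
            s = self._marker_spectrum(seed)
            _, pl = process_spectrum(s, CFG)
            found = pl.mzs
            hits += all(np.min(np.abs(found - t)) <= 0.05 for t in truths)
        assert hits >= 99

    def test_deterministic(self):
        s = self._marker_spectrum(7)
        _, pl1 = process_spectrum(s, CFG)
        _, pl2 = process_spectrum(s, CFG)
        assert [p.mz for p in pl1.peaks] == [p.mz for p in pl2.peaks]

    def test_no_negative_output(self):
        s = self._marker_spectrum(3)
        corrected, pl = process_spectrum(s, CFG)
        assert np.all(corrected.intensity >= 0)
        assert np.all(np.diff(corrected.mz) > 0)
        assert all(p.intensity > 0 for p in pl.peaks)


def test_peaklist_csv_round_trip(tmp_path):
    pl = PeakList("s1", [peak(1105.6, 30, 12.0), peak(1453.7, 10, 5.0)], 30)
    path = tmp_path / "pl.csv"
    write_peaklist_csv(pl, path)
    back = read_peaklist_csv(path)
    assert back.sample_id == "s1"
    assert np.allclose(back.mzs, pl.mzs)


def test_estimate_noise_scale(rng):
    s = uniform_spectrum(np.clip(rng.normal(10, 2.0, 20000), 0, None), step=0.02)
    noise = estimate_noise(s, window=100.0)
    assert noise.shape == s.intensity.shape
    assert np.all(np.abs(noise - 2.0) < 0.5)
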