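"""Spectral processing chain for collagen peptide mass fingerprints.

The chain mirrors standard mMass-style MALDI processing: Savitzky-Golay
smoothing, segment-wise baseline subtraction, S/N-thresholded peak picking
with intensity-weighted centroiding, and greedy deisotoping down to
monoisotopic peaks.  All stages are deterministic for fixed input and config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .spectra_io import ParameterError, Spectrum

__all__ = [
    "PreprocessConfig",
    "Peak",
    "PeakList",
    "smooth",
    "correct_baseline",
    "estimate_noise",
    "pick_peaks",
    "deisotope",
    "process_spectrum",
    "write_peaklist_csv",
    "read_peaklist_csv",
]

#: m/z spacing between adjacent peptide isotope peaks at charge 1 (Th).
ISOTOPE_SPACING = 1.00235


@dataclass(frozen=True)
class PreprocessConfig:
    """Processing parameters for the smoothing → baseline → picking chain.

    Defaults follow routine ZooMS screening practice: S/N threshold 3.5,
    baseline split into 100 segments with zero relative offset, 2nd-order
    Savitzky-Golay smoothing over a 0.2 Th window applied for 1.5 cycles,
    a 0.5% relative-intensity floor, and 80% picking height for centroids.
    """

    sn_threshold: float = 3.5
    baseline_segments: int = 100
    baseline_offset: float = 0.0
    smooth_window: float = 0.2
    smooth_cycles: float = 1.5
    rel_intensity_threshold: float = 0.005
    picking_height: float = 0.80
    isotope_spacing: float = ISOTOPE_SPACING
    isotope_tol: float = 0.05
    noise_window: float = 100.0  # Th, for the sliding MAD noise estimate

    def __post_init__(self) -> None:
        if self.sn_threshold <= 0:
            raise ParameterError("sn_threshold must be > 0")
        if not 0 < self.picking_height < 1:
            raise ParameterError("picking_height must be in (0, 1)")
        if not 0 <= self.rel_intensity_threshold < 1:
            raise ParameterError("rel_intensity_threshold must be in [0, 1)")
        if self.baseline_segments < 1:
            raise ParameterError("baseline_segments must be >= 1")
        if self.smooth_cycles < 0:
            raise ParameterError("smooth_cycles must be >= 0")


@dataclass
class Peak:
    """A centroided peak; after deisotoping, the monoisotopic cluster head."""

    mz: float
    intensity: float
    sn: float
    is_monoisotopic: bool = True
    envelope: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ParameterError("peak intensity must be > 0")
        if self.sn < 0:
            raise ParameterError("peak S/N must be >= 0")


@dataclass
class PeakList:
    """Centroided peaks of one sample, sorted by m/z."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)
    base_peak_intensity: float = 0.0

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def smooth(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Savitzky-Golay smoothing with fractional pass count.

    The window spans ``smooth_window`` Th on the uniform grid (order 2).
    ``floor(cycles)`` full passes are applied; the fractional remainder is a
    convex blend between the k-pass and (k+1)-pass results, e.g. cycles=1.5
    gives the mean of the 1-pass and 2-pass outputs.
    """
    step = s.grid_step()
    wlen = int(round(cfg.smooth_window / step))
    wlen = max(5, wlen + 1 if wlen % 2 == 0 else wlen)
    if wlen >= s.n_points:
        raise ParameterError("smoothing window wider than spectrum")

    k = int(math.floor(cfg.smooth_cycles))
    frac = cfg.smooth_cycles - k
    y = s.intensity
    for _ in range(k):
        y = savgol_filter(y, wlen, polyorder=2)
    if frac > 0:
        y = (1.0 - frac) * y + frac * savgol_filter(y, wlen, polyorder=2)
    return replace(s, intensity=np.clip(y, 0.0, None))


def correct_baseline(
    s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[Spectrum, np.ndarray]:
    """Segment-minimum baseline subtraction.

    The axis is split into ``baseline_segments`` equal windows; each window
    anchors the baseline at its minimum, shifted up by ``baseline_offset``
    times the window's intensity range.  The baseline is the piecewise-linear
    interpolation through the anchors; output is ``max(0, intensity - baseline)``.

    Returns the corrected spectrum and the baseline curve.
    """
    s.grid_step()  # uniform-grid precondition
    n = s.n_points
    nseg = cfg.baseline_segments
    if n < nseg:
        raise ParameterError(f"{n} grid points < {nseg} baseline segments")
    bounds = np.linspace(0, n, nseg + 1).astype(int)
    anchor_x = np.empty(nseg)
    anchor_y = np.empty(nseg)
    for i in range(nseg):
        sl = slice(bounds[i], bounds[i + 1])
        seg = s.intensity[sl]
        j = int(np.argmin(seg))
        anchor_x[i] = s.mz[sl][j]
        anchor_y[i] = seg[j] + cfg.baseline_offset * (seg.max() - seg.min())
    baseline = np.interp(s.mz, anchor_x, anchor_y)
    corrected = np.clip(s.intensity - baseline, 0.0, None)
    return replace(s, intensity=corrected), baseline


def estimate_noise(s: Spectrum, window: float = 100.0) -> np.ndarray:
    """Per-point noise level: 1.4826 x median absolute deviation, windowed.

    The axis is cut into blocks of ``window`` Th; within each block the MAD
    is taken around the block median (so slow baseline shifts do not inflate
    it) and the scaled values are interpolated across block centres.  Noise
    should be estimated on the *raw* profile: smoothing narrows the noise
    band and would bias S/N upward.  A small positive floor avoids division
    by zero on silent regions.
    """
    lo, hi = s.mz[0], s.mz[-1]
    n_blocks = max(1, int(np.ceil((hi - lo) / window)))
    block_size = s.n_points // n_blocks
    if block_size < 4:
        return np.full(s.n_points, 1e-12)
    trimmed = s.intensity[: block_size * n_blocks].reshape(n_blocks, block_size)
    med = np.median(trimmed, axis=1, keepdims=True)
    mads = 1.4826 * np.median(np.abs(trimmed - med), axis=1)
    centres = s.mz[: block_size * n_blocks].reshape(n_blocks, block_size).mean(axis=1)
    noise = np.interp(s.mz, centres, mads)
    positive = noise[noise > 0]
    floor = positive.min() * 1e-3 if positive.size else 1e-12
    return np.clip(noise, max(floor, 1e-12), None)


def pick_peaks(
    s: Spectrum,
    cfg: PreprocessConfig = PreprocessConfig(),
    noise: np.ndarray | float | None = None,
) -> PeakList:
    """S/N-thresholded local-maximum picking with 80%-height centroiding.

    Local maxima with S/N >= ``sn_threshold`` and intensity >= the relative
    floor (fraction of base peak) are kept; the centroid m/z is the
    intensity-weighted mean of contiguous points above ``picking_height``
    times the apex.  An all-zero spectrum yields an empty PeakList.

    ``noise`` is the per-point (or scalar) noise level; pass the estimate
    from the raw profile (see :func:`process_spectrum`).  When omitted it is
    estimated from ``s`` itself, which understates raw noise if ``s`` was
    smoothed.
    """
    base = float(s.intensity.max()) if s.n_points else 0.0
    if base <= 0:
        return PeakList(sample_id=s.sample_id, peaks=[], base_peak_intensity=0.0)
    if noise is None:
        noise = estimate_noise(s, cfg.noise_window)
    noise = np.broadcast_to(np.asarray(noise, dtype=float), s.intensity.shape)
    apexes, _ = find_peaks(s.intensity)
    min_intensity = cfg.rel_intensity_threshold * base
    height_frac = cfg.picking_height
    peaks: list[Peak] = []
    y, x = s.intensity, s.mz
    for idx in apexes:
        apex = y[idx]
        sn = apex / noise[idx]
        if sn < cfg.sn_threshold or apex < min_intensity:
            continue
        thr = height_frac * apex
        left = idx
        while left > 0 and y[left - 1] >= thr and y[left - 1] <= y[left]:
            left -= 1
        right = idx
        while right < y.size - 1 and y[right + 1] >= thr and y[right + 1] <= y[right]:
            right += 1
        sl = slice(left, right + 1)
        centroid = float(np.average(x[sl], weights=y[sl]))
        peaks.append(Peak(mz=centroid, intensity=float(apex), sn=float(sn)))
    return PeakList(sample_id=s.sample_id, peaks=peaks, base_peak_intensity=base)


def deisotope(pl: PeakList, cfg: PreprocessConfig = PreprocessConfig()) -> PeakList:
    """Cluster isotope envelopes and keep one monoisotopic peak per cluster.

    Peaks spaced by ``isotope_spacing`` (+/- ``isotope_tol``) are clustered
    greedily from low m/z; several clusters may be open at once so interleaved
    envelopes separate correctly.  A cluster is not extended past its 3rd
    member by a peak of *rising* intensity — such a peak starts a new cluster
    (overlapping-envelope split rule).  The cluster head (lowest m/z) becomes
    the monoisotopic peak carrying the full envelope.
    """
    spacing, tol = cfg.isotope_spacing, cfg.isotope_tol
    open_clusters: list[list[Peak]] = []
    closed: list[list[Peak]] = []
    for peak in pl.peaks:  # already sorted by m/z
        # close clusters that can no longer be extended
        still_open = []
        for cl in open_clusters:
            if peak.mz > cl[-1].mz + spacing + tol:
                closed.append(cl)
            else:
                still_open.append(cl)
        open_clusters = still_open
        # attach to the best-matching open cluster
        best, best_err = None, tol
        for cl in open_clusters:
            err = abs(peak.mz - (cl[-1].mz + spacing))
            if err <= best_err:
                if len(cl) >= 3 and peak.intensity > cl[-1].intensity:
                    continue  # rising tail after 3rd isotope: split
                best, best_err = cl, err
        if best is not None:
            best.append(peak)
        else:
            open_clusters.append([peak])
    closed.extend(open_clusters)

    mono: list[Peak] = []
    for cl in sorted(closed, key=lambda c: c[0].mz):
        head = cl[0]
        mono.append(
            Peak(
                mz=head.mz,
                intensity=head.intensity,
                sn=head.sn,
                is_monoisotopic=True,
                envelope=[(p.mz, p.intensity) for p in cl],
            )
        )
    return PeakList(
        sample_id=pl.sample_id, peaks=mono, base_peak_intensity=pl.base_peak_intensity
    )


def process_spectrum(
    s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[Spectrum, PeakList]:
    """Full chain smooth → baseline → pick → deisotope.

    Noise is estimated on the raw profile before smoothing, so the S/N
    threshold refers to the acquired noise level.  Returns the smoothed,
    baseline-corrected profile together with the deisotoped monoisotopic
    PeakList.
    """
    noise = estimate_noise(s, cfg.noise_window)
    smoothed = smooth(s, cfg)
    corrected, _ = correct_baseline(smoothed, cfg)
    picked = pick_peaks(corrected, cfg, noise=noise)
    return corrected, deisotope(picked, cfg)


def write_peaklist_csv(pl: PeakList, path) -> None:
    pd.DataFrame(
        {
            "sample_id": pl.sample_id,
            "mz": [p.mz for p in pl.peaks],
            "intensity": [p.intensity for p in pl.peaks],
            "sn": [p.sn for p in pl.peaks],
            "is_monoisotopic": [p.is_monoisotopic for p in pl.peaks],
        }
    ).to_csv(path, index=False)


def read_peaklist_csv(path) -> PeakList:
    df = pd.read_csv(path)
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else Path(str(path)).stem
    peaks = [
        Peak(
            mz=float(r.mz),
            intensity=float(r.intensity),
            sn=float(r.sn),
            is_monoisotopic=bool(r.is_monoisotopic),
        )
        for r in df.itertuples()
    ]
    base = max((p.intensity for p in peaks), default=0.0)
    return PeakList(sample_id=sample_id, peaks=peaks, base_peak_intensity=base)
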