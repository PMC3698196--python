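"""Calibrated backscatter power spectra and linear-regression spectral parameters.

The analysis chain mirrors standard quantitative-ultrasound (QUS) spectral
practice: rectangular regions of interest (ROIs) are gated out of a raw RF
frame, each scan-line segment is Hamming-weighted and Fourier transformed,
line periodograms are averaged in linear power, the averaged spectrum is
divided (in dB: subtracted) by the spectrum of a perfect planar-reflector
calibration echo, and an ordinary-least-squares line is fit to the calibrated
spectrum over the usable band.  The two regression parameters are the
biomarkers of interest:

* spectral slope (SS), dB/MHz — sensitive to effective scatterer size;
* midband fit (MBF), dB — the fitted value at the band center, sensitive to
  scatterer concentration and impedance contrast.

Conventions (documented once, relied on everywhere):

* power dB = 10*log10(mean squared magnitude); amplitude doubling = +6.02 dB;
* sample indices are 0-based with half-open gates [start, stop);
* depth (mm) maps to sample index floor(2*depth/c * fs) using two-way travel
  at the frame's sound speed c (mm/us) and sampling rate fs (MHz);
* line spectra are averaged in linear power before dB conversion;
* per-ROI parameters are averaged arithmetically at the tumor level, spectra
  are never pooled across ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ROISpec",
    "PowerSpectrum",
    "CalibratedSpectrum",
    "SpectralParams",
    "depth_to_sample",
    "gate_roi",
    "windowed_power_spectrum",
    "analysis_band",
    "calibrate",
    "fit_spectral_params",
    "average_spectral_params",
    "tumor_spectral_params",
    "percent_change",
]

DEFAULT_BAND_THRESHOLD_DB = 10.0
DB_FLOOR = -300.0
MIN_GATE_SAMPLES = 64


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest in (depth, line) coordinates.

    depth_start/depth_span are in mm; first_line/n_lines index scan lines.
    """

    depth_start: float
    depth_span: float
    first_line: int
    n_lines: int

    def __post_init__(self) -> None:
        if self.depth_span <= 0:
            raise ValueError("depth_span must be > 0")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.depth_start < 0:
            raise ValueError("depth_start must be >= 0")
        if self.first_line < 0:
            raise ValueError("first_line must be >= 0")


@dataclass(frozen=True)
class PowerSpectrum:
    """Line-averaged power spectrum on a positive-frequency grid (MHz, dB)."""

    frequencies: np.ndarray
    magnitude_db: np.ndarray
    n_lines_averaged: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitude_db, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise ValueError("frequencies and magnitude_db must be equal-length 1-D arrays")
        if f.size and (np.any(np.diff(f) <= 0) or f[0] <= 0):
            raise ValueError("frequency grid must be strictly increasing and positive")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitude_db", m)


@dataclass(frozen=True)
class CalibratedSpectrum:
    """Tissue spectrum relative to the calibration reference, plus fit band."""

    frequencies: np.ndarray
    magnitude_db: np.ndarray
    band: tuple[float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitude_db, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise ValueError("frequencies and magnitude_db must be equal-length 1-D arrays")
        lo, hi = self.band
        if not (lo < hi):
            raise ValueError("band must satisfy f_lo < f_hi")
        if lo < f[0] or hi > f[-1]:
            raise ValueError("band must lie inside the frequency grid")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitude_db", m)


@dataclass(frozen=True)
class SpectralParams:
    """Regression parameters of a calibrated spectrum.

    slope (SS) is in dB/MHz, midband (MBF) in dB at the band center, and
    intercept in dB at 0 MHz; midband == slope*center_frequency + intercept.
    """

    slope: float
    midband: float
    intercept: float
    center_frequency: float
    band: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.band
        if abs(self.center_frequency - 0.5 * (lo + hi)) > 1e-9:
            raise ValueError("center_frequency must be the band midpoint")
        if abs(self.midband - (self.slope * self.center_frequency + self.intercept)) > 1e-6:
            raise ValueError("midband must equal slope*center_frequency + intercept")


def depth_to_sample(depth_mm: float, sound_speed_mm_us: float, sampling_rate_mhz: float) -> int:
    """Map a depth (mm) to a sample index via two-way travel time."""
    return int(np.floor(2.0 * depth_mm / sound_speed_mm_us * sampling_rate_mhz))


def gate_roi(frame, roi: ROISpec) -> np.ndarray:
    """Extract the (n_lines, L) RF segments of an ROI from a frame.

    Raises ValueError naming the offending bound when the ROI falls outside
    the frame.
    """
    lines = np.asarray(frame.lines, dtype=float)
    n_lines, n_samples = lines.shape
    start = depth_to_sample(roi.depth_start, frame.sound_speed, frame.sampling_rate)
    stop = depth_to_sample(roi.depth_start + roi.depth_span, frame.sound_speed, frame.sampling_rate)
    if stop > n_samples:
        raise ValueError(
            f"ROI depth extent ends at sample {stop} but the frame has only {n_samples} samples"
        )
    if roi.first_line + roi.n_lines > n_lines:
        raise ValueError(
            f"ROI line extent ends at line {roi.first_line + roi.n_lines} but the frame has "
            f"only {n_lines} lines"
        )
    return lines[roi.first_line : roi.first_line + roi.n_lines, start:stop]


def windowed_power_spectrum(
    segments, sampling_rate: float, db_floor: float = DB_FLOOR
) -> PowerSpectrum:
    """Hamming-windowed, line-averaged power spectrum of gated RF segments.

    Each segment is multiplied by the L-point (symmetric) Hamming window, the
    squared DFT magnitudes are averaged over lines in linear power, and the
    result is returned in dB on the positive-frequency grid (DC excluded).
    All-zero input is guarded by ``db_floor`` with a warning instead of -inf.
    """
    seg = np.atleast_2d(np.asarray(segments, dtype=float))
    if seg.ndim != 2 or seg.shape[0] < 1:
        raise ValueError("segments must be a non-empty 2-D array (n_lines, L)")
    n_lines, length = seg.shape
    if length < MIN_GATE_SAMPLES:
        raise ValueError(f"gate length {length} is below the minimum of {MIN_GATE_SAMPLES} samples")
    window = np.hamming(length)
    spectra = np.abs(np.fft.rfft(seg * window, axis=1)) ** 2
    power = spectra.mean(axis=0)[1:]  # drop the DC bin
    freqs = np.fft.rfftfreq(length, d=1.0 / sampling_rate)[1:]
    floor = 10.0 ** (db_floor / 10.0)
    if np.any(power <= floor):
        warnings.warn(
            f"power spectrum clipped at the {db_floor} dB floor (all-zero or degenerate input)",
            RuntimeWarning,
            stacklevel=2,
        )
    magnitude_db = 10.0 * np.log10(np.maximum(power, floor))
    return PowerSpectrum(frequencies=freqs, magnitude_db=magnitude_db, n_lines_averaged=n_lines)


def analysis_band(
    reference: PowerSpectrum, threshold_db: float = DEFAULT_BAND_THRESHOLD_DB
) -> tuple[float, float]:
    """Usable analysis band: the contiguous interval around the reference peak
    where the reference power stays within ``threshold_db`` of its maximum.

    The reference must have an interior peak; bands narrower than three bins
    (e.g. a zero threshold) are rejected as degenerate.
    """
    mag = np.asarray(reference.magnitude_db, dtype=float)
    freqs = np.asarray(reference.frequencies, dtype=float)
    peak = int(np.argmax(mag))
    if peak == 0 or peak == mag.size - 1:
        raise ValueError("reference spectrum has no interior peak; cannot define a band")
    cutoff = mag[peak] - threshold_db
    lo = peak
    while lo > 0 and mag[lo - 1] >= cutoff:
        lo -= 1
    hi = peak
    while hi < mag.size - 1 and mag[hi + 1] >= cutoff:
        hi += 1
    if hi - lo + 1 < 3:
        raise ValueError(
            f"analysis band of {hi - lo + 1} bin(s) is degenerate; increase threshold_db"
        )
    return float(freqs[lo]), float(freqs[hi])


def calibrate(
    tissue: PowerSpectrum,
    reference: PowerSpectrum,
    band: tuple[float, float] | None = None,
    band_threshold_db: float = DEFAULT_BAND_THRESHOLD_DB,
) -> CalibratedSpectrum:
    """Divide the tissue spectrum by the reference spectrum (dB subtraction).

    The regression band defaults to :func:`analysis_band` of the reference.
    """
    ft = np.asarray(tissue.frequencies)
    fr = np.asarray(reference.frequencies)
    if ft.shape != fr.shape or not np.allclose(ft, fr):
        raise ValueError("tissue and reference spectra must share an identical frequency grid")
    if band is None:
        band = analysis_band(reference, band_threshold_db)
    return CalibratedSpectrum(
        frequencies=ft.copy(),
        magnitude_db=np.asarray(tissue.magnitude_db) - np.asarray(reference.magnitude_db),
        band=band,
    )


def fit_spectral_params(spectrum: CalibratedSpectrum) -> SpectralParams:
    """Ordinary least squares of calibrated magnitude on frequency over the band."""
    f = spectrum.frequencies
    lo, hi = spectrum.band
    sel = (f >= lo) & (f <= hi)
    if int(sel.sum()) < 3:
        raise ValueError("fewer than 3 frequency bins inside the analysis band")
    slope, intercept = np.polyfit(f[sel], spectrum.magnitude_db[sel], 1)
    fc = 0.5 * (lo + hi)
    return SpectralParams(
        slope=float(slope),
        midband=float(slope * fc + intercept),
        intercept=float(intercept),
        center_frequency=fc,
        band=(lo, hi),
    )


def average_spectral_params(params: Sequence[SpectralParams]) -> SpectralParams:
    """Arithmetic mean of slope and midband across ROIs sharing one band."""
    if not params:
        raise ValueError("no spectral parameters to average")
    band = params[0].band
    fc = params[0].center_frequency
    for p in params[1:]:
        if p.band != band:
            raise ValueError("spectral parameters must share the same analysis band")
    slope = float(np.mean([p.slope for p in params]))
    midband = float(np.mean([p.midband for p in params]))
    return SpectralParams(
        slope=slope,
        midband=midband,
        intercept=midband - slope * fc,
        center_frequency=fc,
        band=band,
    )


def tumor_spectral_params(
    frame,
    reference,
    rois: Sequence[ROISpec],
    band_threshold_db: float = DEFAULT_BAND_THRESHOLD_DB,
) -> tuple[SpectralParams, list[SpectralParams]]:
    """Per-tumor spectral parameters: three ROIs, one shared band, averaged.

    The reference frame is gated at the same depth window as the first ROI
    (all reference lines are used; the calibration echo sits at the focal
    depth, where ROIs are centered).  A single analysis band is derived from
    the reference and shared by every ROI so that per-ROI parameters are
    commensurate; slope and midband are then averaged arithmetically.

    Returns ``(mean_params, per_roi_params)``.
    """
    if len(rois) == 0:
        raise ValueError("at least one ROI is required")
    if len(rois) != 3:
        warnings.warn(
            f"{len(rois)} ROI(s) supplied; the standard protocol averages 3",
            UserWarning,
            stacklevel=2,
        )
    spans = {roi.depth_span for roi in rois}
    if len(spans) != 1:
        raise ValueError("all ROIs must share the same depth span (one spectral grid)")
    ref_roi = ROISpec(
        depth_start=rois[0].depth_start,
        depth_span=rois[0].depth_span,
        first_line=0,
        n_lines=np.asarray(reference.lines).shape[0],
    )
    ref_spectrum = windowed_power_spectrum(gate_roi(reference, ref_roi), reference.sampling_rate)
    band = analysis_band(ref_spectrum, band_threshold_db)
    per_roi = []
    for roi in rois:
        tissue_spectrum = windowed_power_spectrum(gate_roi(frame, roi), frame.sampling_rate)
        per_roi.append(fit_spectral_params(calibrate(tissue_spectrum, ref_spectrum, band=band)))
    return average_spectral_params(per_roi), per_roi


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Percent change from the control mean: 100*(treated - control)/|control|."""
    if control_mean == 0:
        raise ValueError("percent change is undefined for a zero control mean")
    return 100.0 * (treated_mean - control_mean) / abs(control_mean)
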