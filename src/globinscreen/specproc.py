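"""Spectral processing: smoothing, baseline removal, peak picking,
internal-standard m/z recalibration, ppm peak matching and IS normalisation.

The chain mirrors linear-mode MALDI practice for intact proteins: moving-
average (or Savitzky-Golay) smoothing, SNIP iterative-clipping baseline
estimation, local-maximum peak picking against an MAD noise scale, a
one-point multiplicative m/z recalibration on the internal-standard 1+ ion,
greedy nearest-ppm assignment of peaks to (species, charge) slots within a
3000 ppm window, and division of each globin peak intensity by the matched
internal-standard peak intensity.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

from .spectra_io import Spectrum
from .synthcohort import GlobinPanel

DEFAULT_TOLERANCE_PPM = 3000.0
DEFAULT_SNR_MIN = 3.0
DEFAULT_MIN_SPACING = 10.0  # Th
DEFAULT_SNIP_ITERATIONS = 60
DEFAULT_SMOOTH_WINDOW = 5


class ParameterError(ValueError):
    """Invalid processing parameter (e.g. even smoothing window)."""


class CalibrationError(RuntimeError):
    """No internal-standard candidate found; the sample must be flagged."""


class NormalizationError(RuntimeError):
    """No internal-standard assignment available for normalisation."""


@dataclasses.dataclass
class Peak:
    """A detected local maximum: observed m/z, apex height, signal-to-noise."""

    mz_obs: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError(f"peak intensity must be positive, got {self.intensity}")
        if self.snr < 0:
            raise ValueError("peak snr must be nonnegative")


@dataclasses.dataclass
class PeakAssignment:
    """A peak attributed to a (species, charge) slot.

    ``ppm_error`` is signed: (observed - reference)/reference * 1e6.
    ``intensity_norm`` is filled by :func:`normalize_assignments`.
    """

    species: str
    charge: int
    mz_obs: float
    mz_ref: float
    ppm_error: float
    intensity_raw: float
    intensity_norm: Optional[float] = None


def ppm_error(mz_obs: float, mz_ref: float) -> float:
    """Signed relative mass error in parts per million."""
    return (mz_obs - mz_ref) / mz_ref * 1e6


def smooth(
    spectrum: Spectrum,
    window_points: int = DEFAULT_SMOOTH_WINDOW,
    method: Literal["moving_average", "savgol"] = "moving_average",
) -> Spectrum:
    """Smooth intensities on the unchanged m/z axis.

    Moving average is the default; Savitzky-Golay (cubic) is available behind
    the same interface. A constant signal is a fixed point of both.
    """
    w = int(window_points)
    if w < 3 or w % 2 == 0:
        raise ParameterError(f"window_points must be an odd integer >= 3, got {window_points}")
    if w >= len(spectrum):
        raise ParameterError(
            f"window_points {w} must be smaller than the spectrum length {len(spectrum)}"
        )
    if method == "moving_average":
        out = uniform_filter1d(spectrum.intensity, size=w, mode="reflect")
    elif method == "savgol":
        out = savgol_filter(spectrum.intensity, window_length=w, polyorder=min(3, w - 1))
    else:
        raise ParameterError(f"unknown smoothing method {method!r}")
    return Spectrum(spectrum.mz, np.clip(out, 0.0, None), spectrum.sample_id)


def _snip_baseline(intensity: np.ndarray, iterations: int) -> np.ndarray:
    """SNIP baseline estimate in log-log-sqrt space, decreasing clip window."""
    v = np.asarray(intensity, dtype=float)
    y = np.log(np.log(np.sqrt(v + 1.0) + 1.0) + 1.0)
    w = y.copy()
    max_m = min(int(iterations), (v.size - 1) // 2)
    for m in range(max_m, 0, -1):
        clipped = 0.5 * (w[: -2 * m] + w[2 * m :])
        w[m:-m] = np.minimum(w[m:-m], clipped)
    b = (np.exp(np.exp(w) - 1.0) - 1.0) ** 2 - 1.0
    return np.clip(np.minimum(b, v), 0.0, None)


def remove_baseline(
    spectrum: Spectrum, iterations: int = DEFAULT_SNIP_ITERATIONS
) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract the baseline; returns (corrected, baseline).

    corrected + baseline reconstructs the input exactly, the baseline never
    exceeds the input pointwise, and corrected intensities are nonnegative.
    """
    if iterations < 1:
        raise ParameterError("iterations must be >= 1")
    baseline = _snip_baseline(spectrum.intensity, iterations)
    corrected = spectrum.intensity - baseline
    return (
        Spectrum(spectrum.mz, corrected, spectrum.sample_id),
        Spectrum(spectrum.mz, baseline, spectrum.sample_id),
    )


def noise_scale(intensity: np.ndarray) -> float:
    """Robust noise estimate on a baseline-removed spectrum.

    One-sided MAD-type estimate: the 0.8413 quantile of the intensities about
    their median (for symmetric noise this equals 1.4826 x MAD, i.e. one
    standard deviation). Using only the upper half keeps the estimate honest
    when the lower half of the noise has been clipped at zero.
    """
    v = np.asarray(intensity, dtype=float)
    return float(np.quantile(v, 0.8413) - np.median(v))


def _refine_apex(mz: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid apex position and height by 3-point parabolic interpolation."""
    if i == 0 or i == v.size - 1:
        return float(mz[i]), float(v[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid apex
        return float(mz[i]), float(v[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = float(mz[i + 1] - mz[i]) if delta >= 0 else float(mz[i] - mz[i - 1])
    height = float(y1 - 0.25 * (y0 - y2) * delta)
    return float(mz[i] + delta * step), max(height, float(y1))


def pick_peaks(
    spectrum: Spectrum,
    snr_min: float = DEFAULT_SNR_MIN,
    min_spacing: float = DEFAULT_MIN_SPACING,
) -> list[Peak]:
    """Detect local maxima above the SNR threshold on a baseline-removed spectrum.

    Apex heights are measured above the median intensity floor (the residual
    noise pedestal left by baseline removal); positions and heights are
    refined off-grid by parabolic interpolation. Peaks closer than
    ``min_spacing`` (in Th) keep only the taller one. An all-zero spectrum
    yields an empty list.
    """
    v = spectrum.intensity
    idx, _ = find_peaks(v)
    if idx.size == 0:
        return []
    floor = float(np.median(v))
    scale = noise_scale(v)
    heights = v[idx] - floor
    if scale > 0:
        snrs = heights / scale
    else:
        snrs = np.where(heights > 0, np.inf, 0.0)
    keep = snrs >= snr_min
    idx, heights, snrs = idx[keep], heights[keep], snrs[keep]

    # greedy non-maximum suppression, tallest first
    order = np.argsort(-heights, kind="stable")
    kept_mz: list[float] = []
    kept: list[Peak] = []
    for i in order:
        mz_i, apex_i = _refine_apex(spectrum.mz, v, int(idx[i]))
        height_i = apex_i - floor
        if height_i <= 0:
            continue
        if any(abs(mz_i - m) < min_spacing for m in kept_mz):
            continue
        kept_mz.append(mz_i)
        snr_i = float(snrs[i]) if np.isfinite(snrs[i]) else float(height_i / 1e-12)
        kept.append(Peak(mz_obs=mz_i, intensity=height_i, snr=snr_i))
    kept.sort(key=lambda p: p.mz_obs)
    return kept


def calibrate_mz(
    peaks: Sequence[Peak],
    panel: GlobinPanel,
    search_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> tuple[list[Peak], float]:
    """One-point multiplicative m/z recalibration on the internal-standard 1+ ion.

    The IS candidate is the picked peak with the smallest absolute ppm error
    to the IS 1+ reference within ``search_ppm``. Every peak m/z is then
    multiplied by reference/observed, so the IS 1+ error becomes zero by
    construction. Raises :class:`CalibrationError` when no candidate exists.
    """
    ref = panel.mz_ref("internal_standard", 1)
    best = None
    best_abs = np.inf
    for p in peaks:
        err = abs(ppm_error(p.mz_obs, ref))
        if err <= search_ppm and err < best_abs:
            best, best_abs = p, err
    if best is None:
        raise CalibrationError(
            f"no internal-standard 1+ candidate within {search_ppm:.0f} ppm of {ref:.2f}"
        )
    factor = ref / best.mz_obs
    calibrated = [
        Peak(mz_obs=p.mz_obs * factor, intensity=p.intensity, snr=p.snr) for p in peaks
    ]
    return calibrated, float(factor)


def match_peaks(
    peaks: Sequence[Peak],
    panel: GlobinPanel,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> list[PeakAssignment]:
    """Assign calibrated peaks to (species, charge) slots within the ppm window.

    Greedy by ascending absolute ppm error; each peak fills at most one slot
    and each slot takes at most one peak. Unmatched slots are simply absent.
    """
    candidates: list[tuple[float, str, int, int]] = []
    for species in panel.species_masses:
        for z in panel.charges:
            ref = panel.mz_ref(species, z)
            for i, p in enumerate(peaks):
                err = abs(ppm_error(p.mz_obs, ref))
                if err <= tolerance_ppm:
                    candidates.append((err, species, z, i))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

    used_peaks: set[int] = set()
    filled: set[tuple[str, int]] = set()
    assignments: list[PeakAssignment] = []
    for err, species, z, i in candidates:
        if i in used_peaks or (species, z) in filled:
            continue
        used_peaks.add(i)
        filled.add((species, z))
        p = peaks[i]
        ref = panel.mz_ref(species, z)
        assignments.append(
            PeakAssignment(
                species=species,
                charge=z,
                mz_obs=p.mz_obs,
                mz_ref=ref,
                ppm_error=ppm_error(p.mz_obs, ref),
                intensity_raw=p.intensity,
            )
        )
    assignments.sort(key=lambda a: (a.charge, a.species))
    return assignments


def normalize_assignments(
    assignments: Sequence[PeakAssignment],
    mode: Literal["same_charge", "one_plus"] = "same_charge",
) -> tuple[list[PeakAssignment], list[str]]:
    """Divide globin intensities by the internal-standard peak intensity.

    In ``same_charge`` mode each globin is divided by the IS peak of its own
    charge state, falling back to IS 1+ (flag ``is_fallback``) when that
    charge is unmatched; ``one_plus`` always divides by IS 1+. IS slots get
    intensity_norm = 1. Raises :class:`NormalizationError` without any IS.
    """
    is_by_charge = {a.charge: a for a in assignments if a.species == "internal_standard"}
    if not is_by_charge:
        raise NormalizationError("no internal-standard assignment; cannot normalise")
    flags: list[str] = []
    out: list[PeakAssignment] = []
    for a in assignments:
        b = dataclasses.replace(a)
        if a.species == "internal_standard":
            b.intensity_norm = 1.0
        else:
            if mode == "one_plus":
                denom = is_by_charge.get(1)
            else:
                denom = is_by_charge.get(a.charge)
            if denom is None:
                fallback = is_by_charge.get(1) or next(iter(is_by_charge.values()))
                denom = fallback
                flags.append(f"is_fallback:{a.species}_{a.charge}p")
            if denom is None or denom.intensity_raw <= 0:
                raise NormalizationError("internal-standard intensity is nonpositive")
            b.intensity_norm = a.intensity_raw / denom.intensity_raw
        out.append(b)
    return out, flags


@dataclasses.dataclass
class ProcessResult:
    """Outcome of the full per-sample processing chain, with QC flags."""

    assignments: list[PeakAssignment]
    peaks: list[Peak]
    correction_factor: Optional[float]
    qc_flags: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not any(
            f in ("calibration_failed", "is_missing") for f in self.qc_flags
        )


def process_spectrum(
    spectrum: Spectrum,
    panel: GlobinPanel,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_method: Literal["moving_average", "savgol"] = "moving_average",
    snip_iterations: int = DEFAULT_SNIP_ITERATIONS,
    snr_min: float = DEFAULT_SNR_MIN,
    min_spacing: float = DEFAULT_MIN_SPACING,
    search_ppm: float = DEFAULT_TOLERANCE_PPM,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    norm_mode: Literal["same_charge", "one_plus"] = "same_charge",
) -> ProcessResult:
    """Run smoothing, baseline removal, picking, calibration, matching and
    normalisation on one spectrum, converting failures into QC flags."""
    flags: list[str] = []
    smoothed = smooth(spectrum, smooth_window, smooth_method)
    corrected, _ = remove_baseline(smoothed, snip_iterations)
    peaks = pick_peaks(corrected, snr_min=snr_min, min_spacing=min_spacing)
    try:
        peaks, factor = calibrate_mz(peaks, panel, search_ppm=search_ppm)
    except CalibrationError:
        return ProcessResult([], peaks, None, ("calibration_failed",))
    assignments = match_peaks(peaks, panel, tolerance_ppm=tolerance_ppm)
    try:
        assignments, norm_flags = normalize_assignments(assignments, mode=norm_mode)
    except NormalizationError:
        return ProcessResult([], peaks, factor, ("is_missing",))
    flags.extend(norm_flags)
    matched = {(a.species, a.charge) for a in assignments}
    for species in panel.species_masses:
        for z in panel.charges:
            if (species, z) not in matched:
                flags.append(f"slot_missing:{species}_{z}p")
    return ProcessResult(assignments, peaks, factor, tuple(flags))
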