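"""Spectral processing and the three quality filters of the screen.

Order of operations for every sample: calibrate each spectrum to the DSS
reference at 0 ppm, sum the two short-delay replicates, and quantify window
maxima on the shared grid.  Three filters guard each peak:

* stability  — the two short-delay replicates of the protein-metabolite
  sample must agree within 5% (symmetric relative difference), otherwise the
  metabolite is unstable in that protein's presence;
* gain       — a peak whose protein-subtracted intensity exceeds the free
  metabolite reference by more than 0.05 (on the reference scale) gained
  intensity and is discarded;
* S/N        — the residual in the long-delay difference spectrum
  (PM - P - M) must exceed twice the noise floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra import SampleMeasurement, Spectrum1D
from .tables import PeakWindow

logger = logging.getLogger(__name__)

QC_FLAGS = ("unstable", "gained", "low_snr", "unevaluable")


class CalibrationError(RuntimeError):
    """Raised when the DSS reference peak cannot be located."""


@dataclass(frozen=True)
class Thresholds:
    """QC thresholds of the screen (defaults as used throughout)."""

    stability_max: float = 0.05
    gain_min: float = -0.05
    snr_min: float = 2.0
    noise_region: tuple[float, float] = (10.5, 11.0)
    dss_window: tuple[float, float] = (-0.05, 0.05)

    def __post_init__(self) -> None:
        if self.stability_max < 0:
            raise ValueError("stability_max must be >= 0")
        if self.snr_min < 0:
            raise ValueError("snr_min must be >= 0")


@dataclass
class PeakQuant:
    """Quantification of one metabolite peak for one protein-mix sample.

    Stores the raw window maxima of all six spectra plus the maxima of the
    protein-subtracted PM difference spectra (``i_pmp_*``), which are what
    the relaxation factor evaluates: the protein envelope is removed
    pointwise before peak picking, exactly cancelling the protein's own
    contribution instead of comparing maxima taken at different positions.
    """

    protein_id: str
    metabolite_id: str
    window: PeakWindow
    i_m_short: float
    i_m_long: float
    i_p_short: float
    i_p_long: float
    i_pm_short: float
    i_pm_long: float
    i_pmp_short: float
    i_pmp_long: float
    noise_sd: float
    snr: float
    stability_reldiff: float
    gain_value: float
    flags: set = field(default_factory=set)

    def qualifies(self) -> bool:
        return not self.flags


# ----------------------------------------------------------------------


def estimate_noise(
    spec: Spectrum1D, noise_region: tuple[float, float] = (10.5, 11.0)
) -> float:
    """Noise s.d. from a signal-free ppm region after linear de-trending.

    The region must cover at least 10 grid points.  If the region in fact
    contains a peak the estimate is inflated; a warning is logged when the
    residuals look peak-like.
    """
    lo, hi = min(noise_region), max(noise_region)
    vals = spec.window_slice(lo, hi)
    if vals.size < 10:
        raise ValueError(
            f"noise region [{lo}, {hi}] covers only {vals.size} grid points (<10)"
        )
    if np.all(vals == 0.0):
        return 0.0
    x = np.arange(vals.size, dtype=float)
    coeffs = np.polyfit(x, vals, deg=1)
    resid = vals - np.polyval(coeffs, x)
    sd = float(np.std(resid))
    if sd > 0 and float(np.max(np.abs(resid))) > 6.0 * sd:
        logger.warning(
            "noise region [%.3f, %.3f] of %s looks peak-contaminated; "
            "estimate may be inflated", lo, hi, spec.sample_id,
        )
    return sd


def calibrate(
    spec: Spectrum1D,
    reference_window: tuple[float, float] = (-0.05, 0.05),
    noise_region: tuple[float, float] = (10.5, 11.0),
) -> Spectrum1D:
    """Shift a spectrum so its DSS maximum sits at 0.000 ppm.

    On a uniform grid the shift is snapped to a whole number of grid steps
    and applied to the intensity trace (edges zero-filled), so all calibrated
    spectra of a study stay on one shared axis; the residual is at most half
    a grid step.  Fails if no peak rises at least three times above the noise
    floor inside the reference window.
    """
    lo, hi = min(reference_window), max(reference_window)
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    if not mask.any():
        raise CalibrationError("reference window outside spectrum axis")
    vals = spec.intensity[mask]
    noise = estimate_noise(spec, noise_region)
    peak_height = float(vals.max() - np.median(vals))
    if not peak_height > 3.0 * noise:
        raise CalibrationError(
            f"no reference peak above 3x noise in [{lo}, {hi}] "
            f"(height {peak_height:.4g}, noise {noise:.4g})"
        )
    idx_window = np.flatnonzero(mask)
    peak_ppm = float(spec.ppm[idx_window[np.argmax(vals)]])

    diffs = np.diff(spec.ppm)
    step = float(-np.median(diffs))
    uniform = np.allclose(diffs, -step, rtol=0.0, atol=step * 1e-6)
    if uniform:
        k = int(round(peak_ppm / step))
        shift = k * step
        new_int = np.zeros_like(spec.intensity)
        if k >= 0:
            new_int[k:] = spec.intensity[: len(spec.intensity) - k] if k else spec.intensity
        else:
            new_int[:k] = spec.intensity[-k:]
        out = spec.copy_with(intensity=new_int)
    else:
        shift = peak_ppm
        out = spec.copy_with(ppm=spec.ppm - shift)
    out.meta = dict(spec.meta)
    out.meta["calibration_shift_ppm"] = shift
    out.meta["calibrated"] = True
    return out


def calibrate_measurement(
    meas: SampleMeasurement, thresholds: Thresholds = Thresholds()
) -> SampleMeasurement:
    """Calibrate all three spectra of a measurement to the DSS reference."""
    cal = [
        calibrate(s, thresholds.dss_window, thresholds.noise_region)
        for s in (meas.short_a, meas.long, meas.short_b)
    ]
    return SampleMeasurement(
        sample_id=meas.sample_id,
        role=meas.role,
        short_a=cal[0],
        long=cal[1],
        short_b=cal[2],
        protein_id=meas.protein_id,
        mix_id=meas.mix_id,
        long_delay_ms=meas.long_delay_ms,
    )


def sum_short_replicates(a: Spectrum1D, b: Spectrum1D) -> Spectrum1D:
    """Pointwise sum of the two short-delay replicates.

    Summing the two 256-scan short spectra puts them on the scale of the
    single 512-scan long spectrum while averaging time-dependent intensity
    drift.
    """
    if a.spin_lock_ms != 10.0 or b.spin_lock_ms != 10.0:
        raise ValueError("both replicates must use the 10 ms spin lock")
    if not a.same_axis(b):
        raise ValueError("short replicates are on different ppm axes")
    out = a.copy_with(intensity=a.intensity + b.intensity, experiment="t1rho_short_sum")
    out.meta = dict(a.meta)
    out.meta["summed_replicates"] = (a.experiment, b.experiment)
    return out


def stability_reldiff(a: Spectrum1D, b: Spectrum1D, window: PeakWindow) -> float:
    """Symmetric relative difference of the window maxima of two replicates:
    |max_a - max_b| / mean(max_a, max_b).  Infinite if the mean is not
    positive (a dead peak is never considered stable)."""
    ma = a.window_max(window.ppm_lo, window.ppm_hi)
    mb = b.window_max(window.ppm_lo, window.ppm_hi)
    mean = 0.5 * (ma + mb)
    if mean <= 0:
        return float("inf")
    return abs(ma - mb) / mean


def gain_check(i_m_short: float, i_pm_short: float, i_p_short: float) -> float:
    """Intensity-gain diagnostic on the normalised short-delay scale:
    M - (PM - P).  Values below -0.05 mean the peak gained intensity in the
    protein's presence (e.g. through a chemical conversion) and is excluded.
    """
    return i_m_short - (i_pm_short - i_p_short)


def _on_grid(target: Spectrum1D, other: Spectrum1D) -> np.ndarray:
    """Other's intensities on target's grid (linear interpolation if the
    grids differ)."""
    if target.same_axis(other):
        return other.intensity
    # np.interp wants ascending abscissae
    return np.interp(target.ppm[::-1], other.ppm[::-1], other.intensity[::-1])[::-1]


def difference_spectrum(
    pm: Spectrum1D, p: Spectrum1D, m: Spectrum1D | None = None
) -> Spectrum1D:
    """PM - P (- M) on the PM grid; the residual trace used for S/N."""
    diff = pm.intensity - _on_grid(pm, p)
    if m is not None:
        diff = diff - _on_grid(pm, m)
    out = pm.copy_with(intensity=diff)
    out.meta = dict(pm.meta)
    out.meta["difference"] = True
    return out


def quantify_peak(
    m: SampleMeasurement,
    p: SampleMeasurement,
    pm: SampleMeasurement,
    window: PeakWindow,
    thresholds: Thresholds = Thresholds(),
) -> PeakQuant:
    """Quantify one peak window across the M / P / PM sample triple.

    Fills the six window maxima (summed short replicates and long spectra),
    the noise and S/N from the long-delay PM - P - M residual, the replicate
    stability of the PM sample, and the gain diagnostic, then sets the QC
    flags the thresholds imply.
    """
    if not (m.role == "M" and p.role == "P" and pm.role == "PM"):
        raise ValueError("expected roles M, P, PM in that order")
    if not m.long_delay_ms == p.long_delay_ms == pm.long_delay_ms:
        raise ValueError(
            "long delays differ between M/P/PM; the relaxation factor must "
            "compare spectra measured at the same long delay"
        )
    m_short = sum_short_replicates(m.short_a, m.short_b)
    p_short = sum_short_replicates(p.short_a, p.short_b)
    pm_short = sum_short_replicates(pm.short_a, pm.short_b)

    lo, hi = window.ppm_lo, window.ppm_hi
    i_m_short = m_short.window_max(lo, hi)
    i_m_long = m.long.window_max(lo, hi)
    i_p_short = p_short.window_max(lo, hi)
    i_p_long = p.long.window_max(lo, hi)
    i_pm_short = pm_short.window_max(lo, hi)
    i_pm_long = pm.long.window_max(lo, hi)

    # protein-subtracted PM spectra: the envelope cancels pointwise before
    # the window maximum is taken
    diff_short = difference_spectrum(pm_short, p_short)
    diff_long_pm = difference_spectrum(pm.long, p.long)
    i_pmp_short = float(np.max(diff_short.window_slice(lo, hi)))
    i_pmp_long = float(np.max(diff_long_pm.window_slice(lo, hi)))

    reldiff = stability_reldiff(pm.short_a, pm.short_b, window)

    flags: set = set()
    if i_m_short > 0:
        gain = gain_check(1.0, i_pmp_short / i_m_short, 0.0)
    else:
        gain = float("nan")
        flags.add("unevaluable")

    diff_long = difference_spectrum(pm.long, p.long, m.long)
    residual = float(np.max(np.abs(diff_long.window_slice(lo, hi))))
    noise_sd = estimate_noise(diff_long, thresholds.noise_region)
    if noise_sd > 0:
        snr = residual / noise_sd
    else:
        snr = float("inf") if residual > 0 else 0.0

    if reldiff > thresholds.stability_max:
        flags.add("unstable")
    if np.isfinite(gain) and gain < thresholds.gain_min:
        flags.add("gained")
    # snr_min = 0 disables the gate (useful for idealised noise-free data)
    if thresholds.snr_min > 0 and not snr > thresholds.snr_min:
        flags.add("low_snr")

    return PeakQuant(
        protein_id=pm.protein_id,
        metabolite_id=window.metabolite_id,
        window=window,
        i_m_short=i_m_short,
        i_m_long=i_m_long,
        i_p_short=i_p_short,
        i_p_long=i_p_long,
        i_pm_short=i_pm_short,
        i_pm_long=i_pm_long,
        i_pmp_short=i_pmp_short,
        i_pmp_long=i_pmp_long,
        noise_sd=noise_sd,
        snr=snr,
        stability_reldiff=reldiff,
        gain_value=gain,
        flags=flags,
    )
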