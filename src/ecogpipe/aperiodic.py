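"""Parameterization of power spectra into an aperiodic component plus peaks.

The aperiodic (non-oscillatory, 1/f-like) background of an ECoG power spectrum
is modelled knee-free in log-log space,

    log10 PSD(f) = b - chi * log10 f,

where ``b`` is the offset (log10 power at 1 Hz) and ``chi`` the exponent
(positive slope magnitude; a proxy for cortical excitation-inhibition
balance).  Oscillatory peaks riding on the background are modelled as
Gaussians in log-power over linear frequency and removed iteratively before
the final line fit, so narrow-band rhythms do not bias the slope.

Fits are produced over six frequency ranges (1-200, 20-30, 20-40, 30-45,
40-60 and 60-120 Hz); the feature block exposes one offset (from the widest
fit) plus the six exponents.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .spectral import PowerSpectrum

logger = logging.getLogger(__name__)

#: The six fit ranges (Hz) used for the slope features.
FIT_RANGES: tuple[tuple[float, float], ...] = (
    (1.0, 200.0), (20.0, 30.0), (20.0, 40.0),
    (30.0, 45.0), (40.0, 60.0), (60.0, 120.0),
)

#: Gaussian peak FWHM bounds (Hz).
DEFAULT_PEAK_BW_BOUNDS = (1.0, 12.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class FeatureMissingError(ValueError):
    """Raised when a spectrum has too few usable bins for a fit."""


@dataclass
class AperiodicFit:
    fit_range: tuple[float, float]
    offset: float
    exponent: float
    r_squared: float
    n_peaks_removed: int


@dataclass
class PeakParams:
    center_hz: float
    height: float  # log10-power units above the aperiodic line
    bandwidth_hz: float  # FWHM


def _gaussian(f: np.ndarray, height: float, center: float, sigma: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * sigma**2))


def _ols_line(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logf, logp, 1)
    return float(intercept), float(slope)


def _robust_line(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """OLS, then refit on the bins below the 75th residual percentile so
    positive outliers (oscillatory peaks) do not tilt the initial line."""
    intercept, slope = _ols_line(logf, logp)
    resid = logp - (intercept + slope * logf)
    keep = resid <= np.percentile(resid, 75.0)
    if keep.sum() >= 3:
        intercept, slope = _ols_line(logf[keep], logp[keep])
    return intercept, slope


def fit_spectral_model(spectrum_or_freqs, psd: np.ndarray | None = None,
                       fit_range: tuple[float, float] = (1.0, 200.0),
                       retained: np.ndarray | None = None,
                       max_peaks: int = 6, min_peak_height: float = 0.1,
                       peak_bw_bounds: tuple[float, float] = DEFAULT_PEAK_BW_BOUNDS,
                       min_bins: int = 8) -> tuple[AperiodicFit, list[PeakParams]]:
    """Fit one channel's PSD as an aperiodic line plus Gaussian peaks.

    Accepts either a single-channel :class:`PowerSpectrum` or raw
    ``(freqs, psd)`` arrays.  Algorithm: (1) robust log-log line fit;
    (2) iteratively locate the largest positive residual, fit and subtract a
    Gaussian, until ``max_peaks`` or the residual falls below
    ``min_peak_height`` (log10 units); (3) refit the line on the
    peak-subtracted spectrum.  Returns offset = intercept and
    exponent = -slope (positive for decaying spectra).
    """
    if isinstance(spectrum_or_freqs, PowerSpectrum):
        spec = spectrum_or_freqs
        if spec.psd.shape[0] != 1:
            raise ValueError("pass a single-channel spectrum (or raw arrays)")
        freqs, p, ret = spec.freqs, spec.psd[0], spec.retained
    else:
        freqs = np.asarray(spectrum_or_freqs, dtype=float)
        p = np.asarray(psd, dtype=float)
        ret = np.ones_like(freqs, dtype=bool) if retained is None else np.asarray(retained, bool)

    low, high = fit_range
    if not low < high:
        raise ValueError("fit_range must satisfy low < high")
    sel = ret & (freqs >= low) & (freqs <= high) & np.isfinite(p)
    nonpos = sel & ~(p > 0)
    if nonpos.any():
        warnings.warn(f"{int(nonpos.sum())} non-positive PSD bins excluded from fit")
        sel &= p > 0
    if sel.sum() < min_bins:
        raise FeatureMissingError(
            f"only {int(sel.sum())} usable bins in {fit_range} Hz (need >= {min_bins})")

    logf = np.log10(freqs[sel])
    logp = np.log10(p[sel])
    f_lin = freqs[sel]

    intercept, slope = _robust_line(logf, logp)
    resid = logp - (intercept + slope * logf)

    sig_lo, sig_hi = (b * _FWHM_TO_SIGMA for b in peak_bw_bounds)
    sig_hi = min(sig_hi, (high - low) / 2.0)
    sig_lo = min(sig_lo, sig_hi / 2.0)
    peaks: list[PeakParams] = []
    model_peaks = np.zeros_like(resid)
    work = resid.copy()
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        h0 = work[i]
        if h0 < min_peak_height:
            break
        c0 = f_lin[i]
        # crude width guess: distance until the residual halves
        above = work >= h0 / 2.0
        j = i
        while j + 1 < len(work) and above[j + 1]:
            j += 1
        k = i
        while k - 1 >= 0 and above[k - 1]:
            k -= 1
        s0 = np.clip((f_lin[j] - f_lin[k]) * _FWHM_TO_SIGMA + 1e-3, sig_lo, sig_hi)
        try:
            popt, _ = curve_fit(
                _gaussian, f_lin, work, p0=[h0, c0, s0],
                bounds=([min_peak_height / 2.0, low, sig_lo],
                        [2.0 * h0 + 1.0, high, sig_hi]),
                maxfev=2000)
        except RuntimeError:
            break
        g = _gaussian(f_lin, *popt)
        work = work - g
        model_peaks = model_peaks + g
        peaks.append(PeakParams(center_hz=float(popt[1]), height=float(popt[0]),
                                bandwidth_hz=float(popt[2] / _FWHM_TO_SIGMA)))

    intercept, slope = _ols_line(logf, logp - model_peaks)
    fitted = intercept + slope * logf + model_peaks
    ss_res = float(np.sum((logp - fitted) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = AperiodicFit(fit_range=(low, high), offset=float(intercept),
                       exponent=float(-slope), r_squared=float(np.clip(r2, 0.0, 1.0)),
                       n_peaks_removed=len(peaks))
    return fit, peaks


def _range_col(fit_range: tuple[float, float]) -> str:
    return f"slope_{fit_range[0]:g}_{fit_range[1]:g}"


def aperiodic_feature_block(spectrum: PowerSpectrum,
                            ranges: tuple[tuple[float, float], ...] = FIT_RANGES,
                            offset_range: tuple[float, float] = (1.0, 200.0),
                            **fit_kwargs) -> pd.DataFrame:
    """Seven aperiodic feature columns per channel: one offset (from the
    widest fit) and one exponent per fit range.  Channels whose fit fails in a
    range carry NaN there."""
    cols: dict[str, list[float]] = {"offset": []}
    for r in ranges:
        cols[_range_col(r)] = []
    for i, cid in enumerate(spectrum.channel_ids):
        fits: dict[tuple[float, float], AperiodicFit | None] = {}
        for r in set(ranges) | {tuple(offset_range)}:
            try:
                fits[r], _ = fit_spectral_model(
                    spectrum.freqs, spectrum.psd[i], fit_range=r,
                    retained=spectrum.retained, **fit_kwargs)
            except (FeatureMissingError, ValueError):
                logger.warning("channel %s: aperiodic fit missing for %s Hz", cid, r)
                fits[r] = None
        off = fits.get(tuple(offset_range))
        cols["offset"].append(off.offset if off is not None else np.nan)
        for r in ranges:
            f = fits[r]
            cols[_range_col(r)].append(f.exponent if f is not None else np.nan)
    out = pd.DataFrame(cols, index=list(spectrum.channel_ids))
    out.index.name = "channel_id"
    return out
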