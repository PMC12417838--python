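"""Welch power spectra, line-noise bin removal, band powers and per-patient
normalization.

Spectra are estimated with Welch's method (Hann window of two seconds, i.e.
n = 2 x sampling rate samples, 50% overlap), averaged over the artifact-free
segments of each channel.  Bins near the mains frequency and its harmonics are
excluded before any power summation.  Absolute band power integrates the PSD
over the band; relative power divides by the total power over all retained
bins.  For cross-patient comparability each feature column is normalized to
the per-patient maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import Recording, SegmentMask

logger = logging.getLogger(__name__)

#: Canonical band table for power features (Hz, half-open intervals).
POWER_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 29.0),
    "low_gamma": (30.0, 45.0),
    "high_gamma": (55.0, 100.0),
}


@dataclass
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 < low < high")


def default_bands() -> list[BandDefinition]:
    return [BandDefinition(n, lo, hi) for n, (lo, hi) in POWER_BANDS.items()]


@dataclass
class PowerSpectrum:
    """Per-channel Welch PSD on a common frequency grid.

    ``retained`` marks bins kept after line-noise removal; every power
    summation uses retained bins only.  Channels without a long-enough clean
    segment carry NaN rows.
    """

    freqs: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs)
    channel_ids: list[str]
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if self.retained is None:
            self.retained = np.ones_like(self.freqs, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.psd.shape != (len(self.channel_ids), len(self.freqs)):
            raise ValueError("psd shape must be (n_channels, n_freqs)")
        if len(self.retained) != len(self.freqs):
            raise ValueError("retained mask length must equal freqs length")
        finite = self.psd[np.isfinite(self.psd)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError("psd must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(recording: Recording, mask: SegmentMask | None = None,
              window_seconds: float = 2.0,
              overlap_fraction: float = 0.5) -> PowerSpectrum:
    """Hann-tapered, 50%-overlap averaged periodogram per channel.

    Density normalization: sum(psd) * df approximates the signal variance.
    Segments shorter than one window are skipped; a channel with no usable
    segment is marked feature-missing (NaN PSD).
    """
    fs = recording.sampling_rate
    nperseg = int(round(window_seconds * fs))
    noverlap = int(round(nperseg * overlap_fraction))
    if mask is None:
        mask = SegmentMask.full(recording)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    psd = np.full((recording.n_channels, len(freqs)), np.nan)
    for i, cid in enumerate(recording.channel_ids):
        segs = [s for s in mask.intervals.get(cid, []) if s[1] - s[0] >= nperseg]
        if not segs:
            logger.warning("channel %s: no segment >= %d samples, PSD missing",
                           cid, nperseg)
            continue
        acc = np.zeros(len(freqs))
        wsum = 0.0
        for start, end in segs:
            f, p = signal.welch(recording.samples[i, start:end], fs=fs,
                                window="hann", nperseg=nperseg,
                                noverlap=noverlap, detrend="constant")
            w = end - start
            acc += w * p
            wsum += w
        psd[i] = acc / wsum
    return PowerSpectrum(freqs=freqs, psd=psd, channel_ids=list(recording.channel_ids))


def remove_line_noise(spectrum: PowerSpectrum, mains_hz: float = 50.0,
                      half_width_hz: float = 1.0) -> PowerSpectrum:
    """Mark bins within +/- half_width of the mains frequency and every
    harmonic as excluded; power totals then skip them."""
    if mains_hz >= spectrum.freqs.max():
        raise ValueError("mains frequency beyond the computed spectrum")
    retained = spectrum.retained.copy()
    h = mains_hz
    while h <= spectrum.freqs.max() + half_width_hz:
        retained &= np.abs(spectrum.freqs - h) > half_width_hz
        h += mains_hz
    return PowerSpectrum(freqs=spectrum.freqs, psd=spectrum.psd,
                         channel_ids=list(spectrum.channel_ids), retained=retained)


def band_powers(spectrum: PowerSpectrum,
                bands: list[BandDefinition] | None = None,
                total_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Absolute (integrated PSD) and relative band powers over retained bins.

    Bands are half-open [low, high).  The relative denominator is the total
    power over all retained bins (optionally restricted to ``total_range``).
    Returns a frame indexed like ``channel_ids`` with columns ``abs_<band>``,
    ``rel_<band>`` and ``total_power``.
    """
    if bands is None:
        bands = default_bands()
    f = spectrum.freqs
    df = spectrum.df
    total_sel = spectrum.retained.copy()
    if total_range is not None:
        total_sel &= (f >= total_range[0]) & (f < total_range[1])
    total = spectrum.psd[:, total_sel].sum(axis=1) * df
    out = {"channel_id": list(spectrum.channel_ids)}
    for b in bands:
        if b.high > f.max() + df:
            raise ValueError(f"band {b.name} extends beyond the computed spectrum")
        sel = spectrum.retained & (f >= b.low) & (f < b.high)
        if not sel.any():
            warnings.warn(f"band {b.name}: no retained bins, feature missing")
            out[f"abs_{b.name}"] = np.full(len(spectrum.channel_ids), np.nan)
            out[f"rel_{b.name}"] = np.full(len(spectrum.channel_ids), np.nan)
            continue
        absolute = spectrum.psd[:, sel].sum(axis=1) * df
        with np.errstate(invalid="ignore", divide="ignore"):
            relative = np.where(total > 0, absolute / total, np.nan)
        out[f"abs_{b.name}"] = absolute
        out[f"rel_{b.name}"] = relative
    out["total_power"] = total
    return pd.DataFrame(out).set_index("channel_id")


def normalize_per_patient(table: pd.DataFrame, feature_cols: list[str] | None = None,
                          patient_col: str = "patient_id",
                          mode: str = "per_feature") -> pd.DataFrame:
    """Divide each feature column by its per-patient maximum.

    ``mode='per_feature'`` (default) normalizes every column by that column's
    maximum within the patient, keeping features commensurable;
    ``mode='global'`` divides all columns by the patient's single maximum over
    all of them.  A zero (or missing) maximum yields zeros with a warning.
    """
    if patient_col not in table.columns:
        raise ValueError(f"table must carry a {patient_col} column")
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c != patient_col and pd.api.types.is_numeric_dtype(table[c])]
    out = table.copy()
    for pid, idx in table.groupby(patient_col).groups.items():
        block = table.loc[idx, feature_cols]
        if mode == "per_feature":
            denom = block.max(axis=0)
        elif mode == "global":
            denom = pd.Series(block.max(axis=0).max(), index=feature_cols)
        else:
            raise ValueError("mode must be 'per_feature' or 'global'")
        bad = ~(denom > 0)
        if bad.any():
            warnings.warn(
                f"patient {pid}: zero/missing max for {list(denom.index[bad])}; "
                "normalized values set to 0")
        safe = denom.where(~bad, 1.0)
        normed = block.div(safe, axis=1)
        normed.loc[:, bad[bad].index] = 0.0
        out.loc[idx, feature_cols] = normed
    return out
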