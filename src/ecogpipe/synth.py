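"""Synthetic multi-channel ECoG generator with known ground truth.

Each channel is built as

    colored noise (one-sided PSD = 10^b * f^(-chi))
    + band-limited stochastic oscillations (per-compartment RMS amplitudes)
    + 50 Hz line noise and its first harmonic
    + a shared within-compartment background component (phase coupling)

The compartment profiles encode the qualitative electrophysiology of glioma
cortex: the tumoral compartment has elevated relative delta power and
suppressed broadband activity with the strongest internal phase coupling;
the peritumoral compartments have elevated relative beta power and a steeper
aperiodic slope in the 20-40 Hz range; healthy cortex is the baseline.

A companion generator draws biopsy infiltration counts (tumor cells per
250 um^2) whose log-rate is linear in a chosen standardized spectral feature,
with the coefficient calibrated by bisection so that, within the
low-infiltration stratum (<50 cells), the feature correlates with the count at
a requested Spearman rho.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io import COMPARTMENTS, ChannelMeta, Recording

logger = logging.getLogger(__name__)

#: Canonical EEG band intervals (Hz) used for the oscillatory components.
BAND_INTERVALS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 29.0),
    "low_gamma": (30.0, 45.0),
    "high_gamma": (55.0, 100.0),
}


@dataclass
class CompartmentProfile:
    """Generative parameters of one cortical compartment."""

    label: str
    aperiodic_offset: float  # b: log10 one-sided PSD at 1 Hz
    aperiodic_exponent: float  # chi >= 0
    band_amplitudes: dict[str, float]  # band name -> oscillation RMS
    line_noise_amplitude: float = 0.05  # RMS of the 50 Hz component
    coupling_strength: float = 0.0  # within-group shared-background weight

    def __post_init__(self) -> None:
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be >= 0")
        if self.line_noise_amplitude < 0:
            raise ValueError("line_noise_amplitude must be >= 0")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")


def default_profiles() -> dict[str, CompartmentProfile]:
    """Compartment profiles encoding the qualitative group effects.

    Amplitudes are in microvolts (typical awake ECoG runs tens to a couple of
    hundred uV RMS).  Tumoral: dominant delta oscillation, suppressed broadband
    background (lower offset) and weak fast oscillations, strongest coupling.
    Peritumoral (close/far): strong beta oscillation and a steeper aperiodic
    exponent (hence a steeper measured 20-40 Hz slope), intermediate coupling.
    Healthy: baseline 1/f^2 background with moderate alpha/beta, weakest
    coupling.
    """
    return {
        "tumoral": CompartmentProfile(
            label="tumoral", aperiodic_offset=3.0, aperiodic_exponent=2.0,
            band_amplitudes={"delta": 40.0, "theta": 7.0, "alpha": 7.0,
                             "beta": 7.0, "low_gamma": 4.0, "high_gamma": 4.0},
            line_noise_amplitude=3.0, coupling_strength=0.8,
        ),
        "close_peritumoral": CompartmentProfile(
            label="close_peritumoral", aperiodic_offset=3.5, aperiodic_exponent=2.3,
            band_amplitudes={"delta": 30.0, "theta": 15.0, "alpha": 18.0,
                             "beta": 40.0, "low_gamma": 8.0, "high_gamma": 6.0},
            line_noise_amplitude=3.0, coupling_strength=0.4,
        ),
        "far_peritumoral": CompartmentProfile(
            label="far_peritumoral", aperiodic_offset=3.5, aperiodic_exponent=2.25,
            band_amplitudes={"delta": 28.0, "theta": 15.0, "alpha": 18.0,
                             "beta": 38.0, "low_gamma": 8.0, "high_gamma": 6.0},
            line_noise_amplitude=3.0, coupling_strength=0.35,
        ),
        "healthy": CompartmentProfile(
            label="healthy", aperiodic_offset=3.5, aperiodic_exponent=2.0,
            band_amplitudes={"delta": 25.0, "theta": 18.0, "alpha": 22.0,
                             "beta": 22.0, "low_gamma": 8.0, "high_gamma": 6.0},
            line_noise_amplitude=3.0, coupling_strength=0.25,
        ),
    }


#: Contact counts per compartment in the reference cohort (total 710).
DEFAULT_CHANNEL_COUNTS = {
    "tumoral": 121,
    "close_peritumoral": 243,
    "far_peritumoral": 212,
    "healthy": 134,
}


@dataclass
class SynthConfig:
    """Study conditions of a synthetic cohort.

    Defaults: 2 kHz analysis rate, 120 s per contact (recordings last at least
    two minutes per electrode position), reference contact counts per
    compartment, and the default compartment profiles.
    """

    sampling_rate: float = 2000.0
    duration: float = 120.0
    channels_per_compartment: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_COUNTS))
    seed: int = 0
    profiles: dict[str, CompartmentProfile] = field(default_factory=default_profiles)
    n_patients: int = 1
    line_noise_hz: float = 50.0

    def __post_init__(self) -> None:
        n = self.duration * self.sampling_rate
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("duration x sampling_rate must be a positive integer")
        for lab in self.channels_per_compartment:
            if lab not in self.profiles:
                raise ValueError(f"no profile for compartment {lab!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class GroundTruth:
    """Per-channel generative truth for a synthetic recording."""

    labels: dict[str, str]
    offsets: dict[str, float]
    exponents: dict[str, float]
    band_amplitudes: dict[str, dict[str, float]]
    coupling: dict[str, float]  # compartment -> coupling strength

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def generate_colored_noise(exponent: float, offset: float, sampling_rate: float,
                           n_samples: int, seed: int | np.random.Generator = 0,
                           ) -> np.ndarray:
    """Gaussian noise with one-sided PSD 10^offset * f^(-exponent).

    Synthesized by spectral shaping: independent complex-normal Fourier
    coefficients with magnitudes proportional to f^(-exponent/2), inverse
    transformed.  Deterministic given the seed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    psd = np.zeros_like(freqs)
    psd[1:] = 10.0 ** offset * freqs[1:] ** (-exponent)
    # One-sided PSD S relates to rfft coefficients X by S = 2|X|^2 / (fs * N).
    amp = np.sqrt(psd * sampling_rate * n_samples / 2.0)
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    coeffs = amp * z / np.sqrt(2.0)
    coeffs[0] = 0.0
    if n_samples % 2 == 0:
        coeffs[-1] = coeffs[-1].real * np.sqrt(2.0)
    return np.fft.irfft(coeffs, n=n_samples)


def add_band_oscillation(x: np.ndarray, band: tuple[float, float], amplitude: float,
                         sampling_rate: float,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add a band-limited stochastic oscillation of the given RMS amplitude.

    The oscillation is white noise band-filtered to ``band`` and rescaled, so
    it has physiological phase jitter rather than a pure sinusoid's rigidity.
    """
    low, high = band
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq})")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return np.array(x, dtype=float, copy=True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    osc = _band_limited_noise(band, sampling_rate, len(x), rng)
    return np.asarray(x, dtype=float) + amplitude * osc


def _band_limited_noise(band: tuple[float, float], fs: float, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (4th-order Butterworth bandpass)."""
    from .io import zero_phase_filter

    sos = signal.butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)],
                        btype="bandpass", output="sos")
    w = rng.standard_normal(n)
    y = zero_phase_filter(sos, w, fs, band[0])
    rms = np.sqrt(np.mean(y**2))
    return y / (rms + 1e-30)


def generate_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Generate a synthetic cohort recording with known ground truth.

    Channels are grouped by compartment.  Within a compartment with coupling
    strength c, each channel's aperiodic background is
    sqrt(1-c^2)*private + c*shared, which leaves the PSD unchanged while
    setting the within-group coherence (and hence the phase locking) by c.
    """
    n = config.n_samples
    fs = config.sampling_rate
    ss = np.random.SeedSequence(config.seed)
    labels_order = [lab for lab in COMPARTMENTS if lab in config.channels_per_compartment]
    labels_order += [lab for lab in config.channels_per_compartment
                     if lab not in labels_order]

    meta: list[ChannelMeta] = []
    rows: list[np.ndarray] = []
    gt_labels: dict[str, str] = {}
    gt_off: dict[str, float] = {}
    gt_exp: dict[str, float] = {}
    gt_amp: dict[str, dict[str, float]] = {}
    coupling = {lab: config.profiles[lab].coupling_strength for lab in labels_order}

    # Representative distances used for the metadata table, per compartment.
    dist_range = {"close_peritumoral": (1.0, 15.0),
                  "far_peritumoral": (15.0, 30.0),
                  "healthy": (31.0, 60.0)}

    ch_index = 0
    group_seeds = ss.spawn(len(labels_order))
    for lab, gseed in zip(labels_order, group_seeds):
        prof = config.profiles[lab]
        count = config.channels_per_compartment[lab]
        shared_ss, *chan_ss = gseed.spawn(count + 1)
        shared = generate_colored_noise(
            prof.aperiodic_exponent, prof.aperiodic_offset, fs, n,
            np.random.default_rng(shared_ss))
        c = prof.coupling_strength
        for k in range(count):
            rng = np.random.default_rng(chan_ss[k])
            private = generate_colored_noise(
                prof.aperiodic_exponent, prof.aperiodic_offset, fs, n, rng)
            x = np.sqrt(max(0.0, 1.0 - c**2)) * private + c * shared
            for band_name, amp in prof.band_amplitudes.items():
                if amp > 0:
                    x = add_band_oscillation(x, BAND_INTERVALS[band_name], amp, fs, rng)
            if prof.line_noise_amplitude > 0:
                t = np.arange(n) / fs
                phase = rng.uniform(0, 2 * np.pi)
                a = prof.line_noise_amplitude * np.sqrt(2.0)
                x = x + a * np.sin(2 * np.pi * config.line_noise_hz * t + phase)
                x = x + 0.5 * a * np.sin(2 * np.pi * 2 * config.line_noise_hz * t
                                         + rng.uniform(0, 2 * np.pi))
            cid = f"ch{ch_index:03d}"
            pid = f"P{(ch_index % config.n_patients) + 1:02d}"
            if lab == "tumoral":
                cm = ChannelMeta(channel_id=cid, patient_id=pid,
                                 on_tumor_flag=True, label=lab)
            else:
                lo, hi = dist_range[lab]
                d = float(rng.uniform(lo, hi))
                cm = ChannelMeta(channel_id=cid, patient_id=pid,
                                 on_tumor_flag=False, distance_mm=d, label=lab)
            meta.append(cm)
            rows.append(x)
            gt_labels[cid] = lab
            gt_off[cid] = prof.aperiodic_offset
            gt_exp[cid] = prof.aperiodic_exponent
            gt_amp[cid] = dict(prof.band_amplitudes)
            ch_index += 1

    rec = Recording(samples=np.vstack(rows), sampling_rate=fs, channel_meta=meta)
    gt = GroundTruth(labels=gt_labels, offsets=gt_off, exponents=gt_exp,
                     band_amplitudes=gt_amp, coupling=coupling)
    return rec, gt


def generate_infiltration_table(features: pd.DataFrame, effect_feature: str,
                                effect_size: float, n_biopsies: int,
                                seed: int = 0, baseline_rate: float = 12.0,
                                noise_sd: float = 0.4,
                                label_col: str = "label") -> pd.DataFrame:
    """Draw biopsy tumor-cell counts (cells / 250 um^2) tied to a feature.

    Counts are Poisson with log-rate linear in the standardized target feature
    plus Gaussian noise; the linear coefficient is calibrated by bisection so
    that within the low-infiltration stratum (0 < count < 50) the feature
    correlates with the count at approximately the requested Spearman rho.
    Biopsies are sampled from peritumoral channels only.
    """
    if abs(effect_size) > 1:
        raise ValueError("effect_size must be a correlation in [-1, 1]")
    peritumoral = features[features[label_col].isin(
        ["close_peritumoral", "far_peritumoral"])]
    if n_biopsies > len(peritumoral):
        raise ValueError(
            f"n_biopsies={n_biopsies} exceeds {len(peritumoral)} peritumoral channels")
    rng = np.random.default_rng(seed)
    chosen = peritumoral.sample(n=n_biopsies, random_state=int(rng.integers(2**31)))
    z = chosen[effect_feature].to_numpy(dtype=float)
    z = (z - z.mean()) / (z.std() + 1e-30)

    sign = np.sign(effect_size) if effect_size != 0 else 0.0
    beta = 0.0
    if effect_size != 0:
        target = abs(effect_size)
        cal_rng = np.random.default_rng(12345)  # internal calibration stream

        def realized_rho(b: float, reps: int = 300) -> float:
            vals = []
            for _ in range(reps):
                c = _draw_counts(z, sign * b, baseline_rate, noise_sd, cal_rng)
                low = (c > 0) & (c < 50)
                if low.sum() >= 4 and np.unique(c[low]).size > 1:
                    r = stats.spearmanr(z[low], c[low]).statistic
                    if np.isfinite(r):
                        vals.append(sign * r)
            return float(np.mean(vals)) if vals else 0.0

        lo, hi = 0.0, 4.0
        for _ in range(18):
            mid = 0.5 * (lo + hi)
            if realized_rho(mid) < target:
                lo = mid
            else:
                hi = mid
        beta = 0.5 * (lo + hi)

    counts = _draw_counts(z, sign * beta, baseline_rate, noise_sd, rng)
    strata = np.where(counts == 0, "healthy", np.where(counts < 50, "low", "high"))
    return pd.DataFrame({
        "biopsy_id": [f"bx{i:03d}" for i in range(n_biopsies)],
        "channel_id": chosen["channel_id"].to_numpy(),
        "count": counts,
        "stratum": strata,
    })


def _draw_counts(z: np.ndarray, beta: float, baseline_rate: float,
                 noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    log_rate = np.log(baseline_rate) + beta * z + noise_sd * rng.standard_normal(len(z))
    return rng.poisson(np.exp(log_rate)).astype(int)
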