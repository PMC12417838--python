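"""Recording containers, file I/O, zero-phase filtering, resampling, artifact
rejection and distance-based compartment labelling.

The analysis operates on intraoperative electrocorticography (ECoG): multi-channel
voltage traces recorded from subdural strip/grid contacts placed over the tumor,
its margins and healthy cortex.  Contacts are assigned to one of four cortical
compartments — ``tumoral``, ``close_peritumoral``, ``far_peritumoral``,
``healthy`` — either directly (contact over an MRI-positive / macroscopically
suspicious area) or from the distance between the contact and the FLAIR-defined
tumor border.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import struct
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: Compartment labels, ordered from the tumor core outwards.
COMPARTMENTS = ("tumoral", "close_peritumoral", "far_peritumoral", "healthy")

#: Distance cut-offs (mm from the FLAIR tumor border) separating the
#: peritumoral zones.  Intervals are half-open and gap-free: (0, 15] mm is
#: close peritumoral, (15, 30] mm far peritumoral, >30 mm healthy.
CLOSE_PERITUMORAL_MAX_MM = 15.0
FAR_PERITUMORAL_MAX_MM = 30.0


@dataclass
class ChannelMeta:
    """Per-contact metadata.

    ``on_tumor_flag`` marks contacts placed over an MRI-positive area (distance
    is then undefined).  ``acquisition_block`` groups channels recorded
    simultaneously; only channels sharing a block are paired for connectivity.
    """

    channel_id: str
    patient_id: str = "P01"
    on_tumor_flag: bool = False
    distance_mm: float | None = None
    label: str | None = None
    acquisition_block: str = "B01"

    def __post_init__(self) -> None:
        if self.distance_mm is not None and not np.isnan(self.distance_mm):
            if self.distance_mm < 0:
                raise ValueError(
                    f"channel {self.channel_id}: distance_mm must be >= 0"
                )


def label_compartment(meta: ChannelMeta) -> str | None:
    """Assign a compartment label from contact position metadata.

    Tumoral if the contact overlies the tumor; otherwise by distance from the
    tumor border: (0, 15] mm close peritumoral, (15, 30] mm far peritumoral,
    >30 mm healthy.  Returns ``None`` (unlabeled, excluded from group
    statistics) when neither the flag nor a distance is available.
    """
    if meta.on_tumor_flag:
        return "tumoral"
    d = meta.distance_mm
    if d is None or (isinstance(d, float) and np.isnan(d)):
        return None
    if d <= CLOSE_PERITUMORAL_MAX_MM:
        return "close_peritumoral"
    if d <= FAR_PERITUMORAL_MAX_MM:
        return "far_peritumoral"
    return "healthy"


@dataclass
class Recording:
    """Multi-channel recording: ``samples`` is (n_channels, n_samples)."""

    samples: np.ndarray
    sampling_rate: float
    channel_meta: list[ChannelMeta]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_meta) != self.samples.shape[0]:
            raise ValueError(
                f"channel_meta has {len(self.channel_meta)} entries for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def channel_ids(self) -> list[str]:
        return [m.channel_id for m in self.channel_meta]

    @property
    def labels(self) -> list[str | None]:
        return [m.label if m.label is not None else label_compartment(m)
                for m in self.channel_meta]

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.channel_meta:
            rows.append(
                {
                    "channel_id": m.channel_id,
                    "patient_id": m.patient_id,
                    "on_tumor": m.on_tumor_flag,
                    "distance_mm": np.nan if m.distance_mm is None else m.distance_mm,
                    "label": m.label if m.label is not None else label_compartment(m),
                    "acquisition_block": m.acquisition_block,
                }
            )
        return pd.DataFrame(rows)

    def copy_with(self, samples: np.ndarray, sampling_rate: float | None = None) -> "Recording":
        return Recording(
            samples=samples,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            channel_meta=[dataclasses.replace(m) for m in self.channel_meta],
        )


# ---------------------------------------------------------------------------
# Plain two-file format: delimited sample matrix + channel metadata table.
# ---------------------------------------------------------------------------

def write_plain(recording: Recording, out_dir: str | Path) -> Path:
    """Write a recording as text: ``samples.tsv`` (channels x samples, one row
    per channel, full float precision) and ``channels.tsv`` (metadata,
    including the sampling rate).  Returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "samples.tsv", recording.samples, delimiter="\t", fmt="%.17g")
    meta = recording.meta_frame()
    meta["sampling_rate_hz"] = recording.sampling_rate
    meta.to_csv(out / "channels.tsv", sep="\t", index=False)
    return out


def _meta_from_frame(meta: pd.DataFrame) -> list[ChannelMeta]:
    out = []
    for _, row in meta.iterrows():
        d = row.get("distance_mm", np.nan)
        out.append(
            ChannelMeta(
                channel_id=str(row["channel_id"]),
                patient_id=str(row.get("patient_id", "P01")),
                on_tumor_flag=bool(row.get("on_tumor", False)),
                distance_mm=None if pd.isna(d) else float(d),
                label=None if pd.isna(row.get("label", np.nan)) else str(row["label"]),
                acquisition_block=str(row.get("acquisition_block", "B01")),
            )
        )
    return out


def read_recording(data_path: str | Path, metadata_path: str | Path,
                   sampling_rate: float | None = None) -> Recording:
    """Read a recording from an EDF file or a plain sample matrix, joined with
    a delimited channel-metadata table.

    Metadata rows must match the stored channels one-to-one by ``channel_id``;
    a mismatch raises a ``ValueError`` naming the offending channels.
    """
    data_path = Path(data_path)
    metadata_path = Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "channel_id" not in meta.columns:
        raise ValueError("metadata table must have a channel_id column")
    meta["channel_id"] = meta["channel_id"].astype(str)

    if data_path.suffix.lower() == ".edf":
        samples, fs, ch_names = _read_edf(data_path)
    else:
        samples = np.loadtxt(data_path, delimiter="\t", ndmin=2)
        if sampling_rate is not None:
            fs = float(sampling_rate)
        elif "sampling_rate_hz" in meta.columns:
            fs = float(meta["sampling_rate_hz"].iloc[0])
        else:
            raise ValueError(
                "sampling rate not given and metadata lacks sampling_rate_hz"
            )
        ch_names = list(meta["channel_id"])
        if samples.shape[0] != len(meta):
            raise ValueError(
                f"metadata has {len(meta)} rows for {samples.shape[0]} channels"
            )

    missing = [c for c in ch_names if c not in set(meta["channel_id"])]
    extra = [c for c in meta["channel_id"] if c not in set(ch_names)]
    if missing or extra:
        raise ValueError(
            f"channel/metadata mismatch: missing from metadata {missing}, "
            f"unmatched metadata rows {extra}"
        )
    meta = meta.set_index("channel_id").loc[ch_names].reset_index()
    return Recording(samples=samples, sampling_rate=fs,
                     channel_meta=_meta_from_frame(meta))


# ---------------------------------------------------------------------------
# EDF: read through MNE; write through a minimal 16-bit EDF encoder
# (1-second data records, physical units microvolts).
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    return samples, float(raw.info["sfreq"]), list(raw.ch_names)


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write the recording to EDF (16-bit, 1-s records, physical unit uV).

    The duration is truncated to whole seconds; the sampling rate must be an
    integer number of samples per second.
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9 or spr <= 0:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = recording.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_rec * spr < recording.n_samples:
        warnings.warn("EDF export truncates a partial final second")
    nch = recording.n_channels
    x = recording.samples[:, : n_rec * spr]

    pmin = x.min(axis=1)
    pmax = x.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii", "replace")[:n]
        return b + b" " * (n - len(b))

    header = b""
    header += pad("0", 8)
    header += pad("X X X X", 80)
    header += pad("Synthetic recording", 80)
    header += pad("01.01.20", 8) + pad("00.00.00", 8)
    header += pad(str(256 * (nch + 1)), 8)
    header += pad("", 44)
    header += pad(str(n_rec), 8)
    header += pad("1", 8)  # record duration, seconds
    header += pad(str(nch), 4)
    for m in recording.channel_meta:
        header += pad(m.channel_id, 16)
    header += pad("", 80) * nch  # transducer
    header += pad("uV", 8) * nch
    for v in pmin:
        header += pad(f"{v:.6g}"[:8], 8)
    for v in pmax:
        header += pad(f"{v:.6g}"[:8], 8)
    header += pad(str(dmin), 8) * nch
    header += pad(str(dmax), 8) * nch
    header += pad("", 80) * nch  # prefiltering
    header += pad(str(spr), 8) * nch
    header += pad("", 32) * nch

    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            seg = x[:, r * spr : (r + 1) * spr]
            dig = np.round((seg - pmin[:, None]) * scale[:, None] + dmin)
            dig = np.clip(dig, dmin, dmax).astype("<i2")
            fh.write(dig.tobytes())
    return path


# ---------------------------------------------------------------------------
# Filtering / resampling
# ---------------------------------------------------------------------------

def _biquad_steady_state(section: np.ndarray) -> np.ndarray:
    """Unit-step steady state of one direct-form-II-transposed biquad, solved
    in extended precision (the 2x2 system is near-singular for poles close to
    z = 1, where float64 solves lose the state entirely)."""
    b0, b1, b2, _, a1, a2 = (np.longdouble(v) for v in section)
    B0 = b1 - a1 * b0
    B1 = b2 - a2 * b0
    det = (np.longdouble(1) + a1) + a2
    zi0 = (B0 + B1) / det
    return np.array([zi0, B1 - a2 * zi0], dtype=np.longdouble)


def zero_phase_filter(sos: np.ndarray, x: np.ndarray, sampling_rate: float,
                      low_hz: float) -> np.ndarray:
    """Forward-backward filtering robust to very low band edges.

    Runs the biquad cascade in extended precision with even-reflection padding
    scaled to the lowest band edge and steady-state initial conditions: for
    edges like 0.1 Hz at a 2 kHz rate the standard float64 filtfilt injects
    corner-frequency artifacts orders of magnitude above the stopband floor.
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x).astype(np.longdouble)
    n = X.shape[1]
    padlen = int(min(n - 1, max(100, 6.0 * sampling_rate / max(low_hz, 1e-6))))
    left = X[:, padlen:0:-1]
    right = X[:, -2:-2 - padlen:-1]
    Y = np.concatenate([left, X, right], axis=1)
    sos_hi = sos.astype(np.longdouble)
    zis = [_biquad_steady_state(s) for s in sos]

    def run(arr: np.ndarray) -> np.ndarray:
        for s, zi in zip(sos_hi, zis):
            arr, _ = signal.lfilter(s[:3], s[3:], arr, axis=1,
                                    zi=zi[None, :] * arr[:, :1])
        return arr

    Y = run(Y)
    Y = run(Y[:, ::-1])[:, ::-1]
    out = Y[:, padlen: padlen + n].astype(float)
    return out[0] if one_d else out


def design_bandpass(sampling_rate: float, low_hz: float, high_hz: float,
                    order: int = 4, stopband_atten_db: float = 40.0) -> np.ndarray:
    """Chebyshev type II bandpass as second-order sections."""
    nyq = sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"passband ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyq} Hz)"
        )
    try:
        return signal.cheby2(order, stopband_atten_db,
                             [low_hz / nyq, high_hz / nyq],
                             btype="bandpass", output="sos")
    except Exception as exc:  # pragma: no cover - scipy raises rarely here
        raise ValueError(
            f"filter design failed at order {order}: {exc}; "
            "try a lower order or wider band"
        ) from exc


def bandpass_zero_phase(recording: Recording, low_hz: float, high_hz: float,
                        order: int = 4,
                        stopband_atten_db: float = 40.0) -> Recording:
    """Forward-backward (zero net phase shift) Chebyshev type II bandpass.

    The filter is applied once forward and once backward along time, so phase
    distortion cancels and the effective stopband attenuation doubles.
    """
    sos = design_bandpass(recording.sampling_rate, low_hz, high_hz,
                          order, stopband_atten_db)
    out = zero_phase_filter(sos, recording.samples, recording.sampling_rate, low_hz)
    return recording.copy_with(out)


def resample(recording: Recording, target_hz: float) -> Recording:
    """Polyphase resampling (anti-alias filtered) to the analysis rate."""
    fs = recording.sampling_rate
    if target_hz > fs:
        raise ValueError("target rate exceeds source rate")
    if abs(target_hz - fs) < 1e-12:
        return recording.copy_with(recording.samples.copy())
    ratio = Fraction(target_hz / fs).limit_denominator(10000)
    out = signal.resample_poly(recording.samples, ratio.numerator,
                               ratio.denominator, axis=1)
    return recording.copy_with(out, sampling_rate=target_hz)


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------

@dataclass
class SegmentMask:
    """Retained half-open sample intervals [start, end) per channel.

    Channels flagged noisy (less than ``min_retained_seconds`` survive) carry
    an empty interval list and appear in ``removed_channels``.
    """

    intervals: dict[str, list[tuple[int, int]]]
    removed_channels: list[str] = field(default_factory=list)
    n_samples: int = 0
    sampling_rate: float = 0.0

    def retained_seconds(self, channel_id: str) -> float:
        return sum(e - s for s, e in self.intervals.get(channel_id, [])) / self.sampling_rate

    def retained_fraction(self, channel_id: str) -> float:
        if self.n_samples == 0:
            return 0.0
        return sum(e - s for s, e in self.intervals.get(channel_id, [])) / self.n_samples

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_samples": self.n_samples,
            "sampling_rate": self.sampling_rate,
            "removed_channels": self.removed_channels,
            "intervals": {k: [list(t) for t in v] for k, v in self.intervals.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentMask":
        doc = json.loads(Path(path).read_text())
        return cls(
            intervals={k: [tuple(t) for t in v] for k, v in doc["intervals"].items()},
            removed_channels=doc["removed_channels"],
            n_samples=doc["n_samples"],
            sampling_rate=doc["sampling_rate"],
        )

    @classmethod
    def full(cls, recording: Recording) -> "SegmentMask":
        return cls(
            intervals={c: [(0, recording.n_samples)] for c in recording.channel_ids},
            n_samples=recording.n_samples,
            sampling_rate=recording.sampling_rate,
        )


def reject_artifacts(recording: Recording, amplitude_z_threshold: float = 6.0,
                     flatline_epsilon: float = 1e-15,
                     window_seconds: float = 1.0,
                     min_retained_seconds: float = 10.0) -> SegmentMask:
    """Exclude artifactual 1-second windows and flatline/noisy channels.

    A window is rejected when the robust z-score (median / MAD across the
    channel's windows) of its peak absolute amplitude exceeds the threshold, or
    when its variance falls below ``flatline_epsilon``.  Channels retaining
    less than ``min_retained_seconds`` are removed entirely.
    """
    if amplitude_z_threshold <= 0 or flatline_epsilon <= 0:
        raise ValueError("thresholds must be positive")
    fs = recording.sampling_rate
    win = int(round(window_seconds * fs))
    n_win = recording.n_samples // win
    intervals: dict[str, list[tuple[int, int]]] = {}
    removed: list[str] = []
    for i, cid in enumerate(recording.channel_ids):
        x = recording.samples[i, : n_win * win].reshape(n_win, win)
        peaks = np.abs(x).max(axis=1)
        var = x.var(axis=1)
        med = np.median(peaks)
        mad = np.median(np.abs(peaks - med))
        z = (peaks - med) / (1.4826 * mad + 1e-30)
        keep = (z <= amplitude_z_threshold) & (var >= flatline_epsilon)
        segs: list[tuple[int, int]] = []
        for w in range(n_win):
            if keep[w]:
                start, end = w * win, (w + 1) * win
                if segs and segs[-1][1] == start:
                    segs[-1] = (segs[-1][0], end)
                else:
                    segs.append((start, end))
        retained = sum(e - s for s, e in segs) / fs
        if retained < min_retained_seconds:
            removed.append(cid)
            intervals[cid] = []
            logger.warning("channel %s noisy, removed (%.1f s retained)", cid, retained)
        else:
            intervals[cid] = segs
    return SegmentMask(intervals=intervals, removed_channels=removed,
                       n_samples=recording.n_samples, sampling_rate=fs)
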