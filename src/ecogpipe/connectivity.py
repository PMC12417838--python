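"""Phase-locking value (PLV) connectivity between simultaneous channels.

For each canonical band the signals are zero-phase Chebyshev-II bandpass
filtered, the instantaneous phase is taken from the Hilbert analytic signal,
and the PLV between two channels is the modulus of the time-averaged unit
phasor of their phase difference:

    PLV = | mean_t exp(i (phi_1(t) - phi_2(t))) |  in [0, 1].

PLV is 1 for perfectly locked signals (including any fixed lag), and for
independent phases its sample mean decays as sqrt(pi / (4 N)).  One second is
trimmed from each end after filtering to drop filter transients.  Only
channels sharing an acquisition block (recorded simultaneously) are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import COMPARTMENTS, Recording, design_bandpass, zero_phase_filter

logger = logging.getLogger(__name__)

#: Band table used for connectivity (beta runs to 30 Hz here, unlike the
#: power-feature table where it ends at 29 Hz; both are kept verbatim).
PLV_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 45.0),
    "high_gamma": (55.0, 100.0),
}


@dataclass
class PLVMatrix:
    band: str
    channel_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]
    n_samples_used: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channel_ids,
                            columns=self.channel_ids)


def instantaneous_phase(recording: Recording, band: tuple[float, float],
                        order: int = 4, stopband_atten_db: float = 40.0,
                        edge_trim_seconds: float = 1.0) -> np.ndarray:
    """Per-sample analytic-signal phase in (-pi, pi] after zero-phase
    Chebyshev-II bandpass filtering; edges trimmed against filter transients.

    Constant channels have no defined phase and are returned as NaN rows.
    """
    fs = recording.sampling_rate
    low, high = band
    sos = design_bandpass(fs, low, high, order, stopband_atten_db)
    filtered = zero_phase_filter(sos, recording.samples, fs, low)
    analytic = signal.hilbert(filtered, axis=1)
    phase = np.angle(analytic)
    trim = int(round(edge_trim_seconds * fs))
    if 2 * trim >= phase.shape[1]:
        raise ValueError("recording too short for the requested edge trim")
    phase = phase[:, trim: phase.shape[1] - trim]
    const = recording.samples.std(axis=1) == 0
    if const.any():
        logger.warning("constant channels flagged (phase undefined): %s",
                       [c for c, f in zip(recording.channel_ids, const) if f])
        phase[const] = np.nan
    return phase


def plv(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLV of two equal-length phase sequences."""
    phase_i = np.asarray(phase_i, float)
    phase_j = np.asarray(phase_j, float)
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase sequences must have equal length")
    return float(np.abs(np.mean(np.exp(1j * (phase_i - phase_j)))))


def plv_matrix(recording: Recording, band_name: str,
               band: tuple[float, float] | None = None,
               **phase_kwargs) -> PLVMatrix:
    """All-pairs PLV for one band.

    Pairs of channels from different acquisition blocks (not recorded
    simultaneously) are NaN; the diagonal is exactly 1.
    """
    if band is None:
        band = PLV_BANDS[band_name]
    phases = instantaneous_phase(recording, band, **phase_kwargs)
    n = phases.shape[1]
    z = np.exp(1j * phases)
    z[~np.isfinite(phases)] = np.nan
    with np.errstate(invalid="ignore"):
        vals = np.abs(z @ z.conj().T) / n
    vals = np.clip(vals, 0.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    blocks = [m.acquisition_block for m in recording.channel_meta]
    for i in range(len(blocks)):
        for j in range(len(blocks)):
            if i != j and blocks[i] != blocks[j]:
                vals[i, j] = np.nan
    return PLVMatrix(band=band_name, channel_ids=list(recording.channel_ids),
                     values=vals, n_samples_used=n)


@dataclass
class CompartmentPLVSummary:
    band: str
    matrix: pd.DataFrame  # label x label mean PLV

    def within(self, label: str) -> float:
        return float(self.matrix.loc[label, label])


def compartment_plv_summary(plvm: PLVMatrix, labels: list[str],
                            label_order: tuple[str, ...] = COMPARTMENTS,
                            ) -> CompartmentPLVSummary:
    """Mean PLV within and between compartments.

    Diagonal blocks average the distinct within-group pairs only (a group with
    fewer than two channels is reported missing); off-diagonal blocks average
    every cross pair.
    """
    if len(labels) != len(plvm.channel_ids):
        raise ValueError("one label per channel required")
    present = [g for g in label_order if g in labels]
    present += sorted(set(labels) - set(present))
    vals = plvm.values
    out = pd.DataFrame(np.nan, index=present, columns=present)
    idx = {g: np.flatnonzero(np.asarray(labels, object) == g) for g in present}
    for a in present:
        for b in present:
            ia, ib = idx[a], idx[b]
            if a == b:
                if len(ia) < 2:
                    continue
                block = vals[np.ix_(ia, ia)]
                triu = block[np.triu_indices(len(ia), k=1)]
                out.loc[a, b] = np.nanmean(triu)
            else:
                out.loc[a, b] = np.nanmean(vals[np.ix_(ia, ib)])
    return CompartmentPLVSummary(band=plvm.band, matrix=out)
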