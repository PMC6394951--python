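"""Band decomposition, instantaneous phase, and the phase lag index.

The phase lag index (PLI) between two signals is::

    PLI = | < sign(dphi(t_k)) > |

the absolute time-average of the sign of the wrapped instantaneous phase
difference.  It is 0 for a phase difference symmetric around zero (no
consistent nonzero lag, including any zero-lag mixture of a common
source) and 1 for a constant nonzero lag.  Phase differences are wrapped
to (-pi, pi] before taking the sign, which makes the statistic symmetric
in its arguments; sign(0) counts as 0.

Connectivity matrices are computed per epoch and then averaged across
epochs for each subject, condition, and band.  Band filters are
linear-phase Kaiser-window FIRs with a transition width of 25% of the
band width, identical across channels; half the filter length is trimmed
from each end of the phase series before the PLI to keep filter edge
transients out of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = [
    "DEFAULT_BANDS",
    "ConnMatrix",
    "design_band_fir",
    "band_filter",
    "instantaneous_phase",
    "wrap_phase",
    "pli",
    "pli_matrix",
    "connectivity_matrices",
]

#: Canonical EEG band limits (Hz).
DEFAULT_BANDS: Mapping[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "low_alpha": (8.0, 10.0),
    "high_alpha": (10.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class ConnMatrix:
    """Symmetric ROI x ROI PLI adjacency for one subject/condition/band."""

    values: np.ndarray
    band: str
    labels: Sequence[str] = ()
    subject: str = ""
    condition: str = ""
    n_epochs: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("PLI values must lie in [0, 1]")
        self.values = v
        self.labels = list(self.labels) or [f"ROI{r:02d}" for r in range(v.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def design_band_fir(low: float, high: float, fs: float,
                    atten_db: float = 20.0) -> np.ndarray:
    """Kaiser FIR band-pass whose passband fully covers [low, high].

    The transition band is 25% of the band width on each side, placed
    outside the nominal band (cutoffs at low - tw/2 and high + tw/2) so
    that tones at the band edges are passed at near-unity gain.
    """
    nyq = fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) outside (0, fs/2)")
    tw = 0.25 * (high - low)
    numtaps, beta = signal.kaiserord(atten_db, tw / nyq)
    if numtaps % 2 == 0:
        numtaps += 1
    lo_cut = max(low - tw / 2.0, 0.05 * low)
    hi_cut = min(high + tw / 2.0, 0.999 * nyq)
    return signal.firwin(numtaps, [lo_cut, hi_cut],
                         window=("kaiser", beta), pass_zero=False, fs=fs)


def band_filter(epochs: EpochSet, band: tuple[float, float],
                atten_db: float = 20.0) -> EpochSet:
    """Apply one narrowband FIR to every channel of every epoch."""
    coeffs = design_band_fir(band[0], band[1], epochs.fs, atten_db=atten_db)
    if coeffs.size >= epochs.n_samples:
        raise ValueError(
            f"filter length {coeffs.size} exceeds epoch length "
            f"{epochs.n_samples}; band ({band[0]}, {band[1]}) Hz is too "
            f"narrow for this epoch duration"
        )
    shape = (1, 1, coeffs.size)
    out = epochs.copy()
    out.data = signal.fftconvolve(epochs.data, coeffs.reshape(shape),
                                  mode="same", axes=-1)
    out.meta = {**epochs.meta, "band": tuple(band), "filter_taps": coeffs.size}
    return out


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal along the last axis, in (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    phase = np.angle(signal.hilbert(x, axis=-1))
    # np.angle returns [-pi, pi]; map -pi to +pi for the (-pi, pi] convention
    phase = np.where(phase == -np.pi, np.pi, phase)
    return phase


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (-pi, pi]."""
    w = np.mod(dphi + np.pi, 2.0 * np.pi) - np.pi   # [-pi, pi)
    return np.where(w == -np.pi, np.pi, w)


def pli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase lag index of two equal-length phase series."""
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"phase series shapes differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.sign(wrap_phase(a - b)))))


def pli_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLI from a (channels x samples) phase array."""
    phases = np.asarray(phases, dtype=float)
    d = wrap_phase(phases[:, None, :] - phases[None, :, :])
    m = np.abs(np.mean(np.sign(d), axis=-1))
    np.fill_diagonal(m, 0.0)
    return m


def connectivity_matrices(
    roi_epochs: EpochSet,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
    atten_db: float = 20.0,
    trim: int | None = None,
) -> list[ConnMatrix]:
    """Per-band epoch-averaged PLI adjacency matrices.

    For each band: filter every epoch, extract analytic phases, trim
    ``trim`` samples (default: half the band filter length) from each end,
    compute the PLI per ROI pair per epoch, and average across epochs.
    """
    if roi_epochs.n_channels < 2:
        raise ValueError("need at least 2 ROIs")
    if roi_epochs.n_epochs < 1:
        raise ValueError("need at least 1 epoch")
    out: list[ConnMatrix] = []
    for name, band in bands.items():
        filtered = band_filter(roi_epochs, band, atten_db=atten_db)
        t = filtered.meta["filter_taps"] // 2 if trim is None else int(trim)
        if 2 * t >= roi_epochs.n_samples - 1:
            raise ValueError(
                f"trim of {t} samples per side leaves no interior samples "
                f"for band {name!r}"
            )
        phases = instantaneous_phase(filtered.data)
        if t:
            phases = phases[..., t:-t]
        acc = np.zeros((roi_epochs.n_channels, roi_epochs.n_channels))
        for e in range(roi_epochs.n_epochs):
            acc += pli_matrix(phases[e])
        acc /= roi_epochs.n_epochs
        out.append(ConnMatrix(values=acc, band=name, labels=roi_epochs.labels,
                              subject=roi_epochs.subject,
                              condition=roi_epochs.condition,
                              n_epochs=roi_epochs.n_epochs))
    return out
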