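"""Broadband filtering, epoch segmentation, and artifact rejection.

The default broadband filter reproduces a Kaiser-window FIR band-pass of
0.5-45 Hz with beta = 5.65 and 4530 taps at 1 kHz (adjusted to the nearest
odd length so the filter is exactly linear-phase type I).  Filtering is
single-pass with group-delay compensation rather than forward-backward:
identical filters on every channel leave phase differences untouched
either way, but a single documented convention keeps phase series
reproducible.

Epoch windows are half-open ``[start, end)`` in samples, tiled from the
start of the recording with the trailing remainder discarded.  "Amplitude
change" for rejection is within-epoch peak-to-peak per channel, the usual
EEGLAB-style threshold semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = [
    "FilterSpec",
    "design_bandpass",
    "apply_fir",
    "segment_epochs",
    "reject_artifacts",
    "exclude_event_epochs",
]


@dataclass(frozen=True)
class FilterSpec:
    """Kaiser-window FIR band-pass specification."""

    low: float = 0.5
    high: float = 45.0
    taps: int = 4530
    kaiser_beta: float = 5.65
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high < self.fs / 2.0):
            raise ValueError(
                f"band edges ({self.low}, {self.high}) must satisfy "
                f"0 < low < high < fs/2 = {self.fs / 2.0}"
            )
        if self.taps < 3:
            raise ValueError("need at least 3 taps")

    @property
    def taps_odd(self) -> int:
        """Tap count adjusted to odd for a symmetric type-I FIR."""
        return self.taps if self.taps % 2 == 1 else self.taps + 1


def design_bandpass(spec: FilterSpec) -> np.ndarray:
    """Linear-phase FIR band-pass coefficients for ``spec``."""
    return signal.firwin(
        spec.taps_odd,
        [spec.low, spec.high],
        window=("kaiser", spec.kaiser_beta),
        pass_zero=False,
        fs=spec.fs,
    )


def apply_fir(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Filter along the last axis, compensating the FIR group delay.

    ``mode='same'`` with an odd symmetric kernel centers the output, so a
    sample's filtered value is aligned with its input time.
    """
    x = np.asarray(x, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size % 2 != 1:
        raise ValueError("expected an odd-length (type-I) FIR kernel")
    if coeffs.ndim != 1:
        raise ValueError("coefficients must be 1-D")
    shape = [1] * x.ndim
    shape[-1] = coeffs.size
    return signal.fftconvolve(x, coeffs.reshape(shape), mode="same", axes=-1)


def segment_epochs(
    continuous: np.ndarray,
    fs: float,
    epoch_ms: float = 2048.0,
    labels=None,
    subject: str = "",
    condition: str = "",
) -> EpochSet:
    """Tile a continuous recording into consecutive non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded.  A
    recording shorter than one epoch yields an empty EpochSet and a
    warning (``meta['short_recording'] = True``).
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_chan, n_total = continuous.shape
    n_samp = int(round(epoch_ms * fs / 1000.0))
    n_epochs = n_total // n_samp
    if labels is None:
        labels = [f"CH{c:02d}" for c in range(n_chan)]
    meta = {"epoch_ms": epoch_ms}
    if n_epochs == 0:
        warnings.warn(
            f"recording of {n_total} samples shorter than one epoch ({n_samp})",
            stacklevel=2,
        )
        meta["short_recording"] = True
        data = np.empty((0, n_chan, n_samp))
    else:
        data = (
            continuous[:, : n_epochs * n_samp]
            .reshape(n_chan, n_epochs, n_samp)
            .transpose(1, 0, 2)
            .copy()
        )
    return EpochSet(data=data, fs=fs, labels=labels,
                    subject=subject, condition=condition, meta=meta)


def reject_artifacts(
    epochs: EpochSet, threshold_uv: float = 100.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs whose peak-to-peak amplitude exceeds the threshold.

    An epoch is rejected iff max - min > ``threshold_uv`` on any channel.
    Returns the retained epochs and a boolean mask (True = kept).
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if epochs.n_epochs == 0:
        return epochs.copy(), np.zeros(0, dtype=bool)
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (epochs, channels)
    keep = ~(ptp > threshold_uv).any(axis=1)
    return epochs.select_epochs(keep), keep


def exclude_event_epochs(
    epochs: EpochSet,
    event_times_ms,
    response_times_ms=(),
    start_ms: float = 0.0,
) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs whose half-open window overlaps any event or response.

    Epoch ``k`` covers ``[start_ms + k*L, start_ms + (k+1)*L)`` on the
    recording clock, ``L`` the epoch duration.  A time landing exactly on a
    boundary belongs to the later epoch.
    """
    ev = np.asarray(list(event_times_ms), dtype=float).ravel()
    resp = np.asarray(list(response_times_ms), dtype=float).ravel()
    times = np.concatenate([ev, resp]) if ev.size or resp.size else np.empty(0)
    keep = np.ones(epochs.n_epochs, dtype=bool)
    L = epochs.epoch_ms
    for t in np.atleast_1d(times):
        k = int(np.floor((t - start_ms) / L))
        if 0 <= k < epochs.n_epochs:
            keep[k] = False
    return epochs.select_epochs(keep), keep
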