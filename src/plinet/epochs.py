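"""Epoched multichannel time series container."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Fixed-length epochs of a multichannel recording.

    Parameters
    ----------
    data:
        Array of shape ``(n_epochs, n_channels, n_samples)``.  Units are
        microvolts at sensor level or arbitrary current-density units at
        ROI/source level.
    fs:
        Sampling rate in Hz.
    labels:
        One unique name per channel/ROI.
    subject, condition:
        Identifiers carried through the pipeline.
    """

    data: np.ndarray
    fs: float
    labels: Sequence[str]
    subject: str = ""
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (epochs, channels, samples), got shape {self.data.shape}"
            )
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[1]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Within-epoch sample times in seconds."""
        return np.arange(self.n_samples) / self.fs

    def select_epochs(self, mask_or_idx) -> "EpochSet":
        return replace(self, data=self.data[np.asarray(mask_or_idx)])

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), meta=dict(self.meta))
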