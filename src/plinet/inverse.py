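"""Simplified standardized minimum-norm (sLORETA-style) source estimation.

The inverse stage maps sensor-level epochs back to source space through a
user-supplied lead field and aggregates voxel estimates into ROI time
series.  Dipoles are scalar (fixed orientation, one value per voxel) and
the noise covariance is taken as identity; the regularization parameter is
expressed relative to the mean eigenvalue of the sensor Gram matrix so that
its meaning does not depend on the scaling of the lead field.

sLORETA standardization divides each voxel's minimum-norm estimate by the
square root of the corresponding resolution-matrix diagonal, which gives
zero localization error for noiseless point sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .epochs import EpochSet

__all__ = ["LeadField", "minimum_norm_operator", "roi_timeseries"]


@dataclass
class LeadField:
    """Linear forward operator: sensors x voxels gain matrix plus ROI map."""

    gain: np.ndarray                      # (n_sensors, n_voxels)
    voxel_roi_map: Sequence[str]          # one ROI label per voxel
    roi_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("lead field gain must be 2-D (sensors x voxels)")
        self.voxel_roi_map = list(self.voxel_roi_map)
        if len(self.voxel_roi_map) != self.gain.shape[1]:
            raise ValueError("voxel_roi_map length must equal the voxel count")
        if np.any(np.all(self.gain == 0.0, axis=0)):
            raise ValueError("lead field contains an all-zero voxel column")
        if self.roi_labels is None:
            # first-appearance order keeps the map deterministic
            seen: dict[str, None] = {}
            for r in self.voxel_roi_map:
                seen.setdefault(r, None)
            self.roi_labels = list(seen)
        else:
            self.roi_labels = list(self.roi_labels)
            missing = set(self.voxel_roi_map) - set(self.roi_labels)
            if missing:
                raise ValueError(f"voxels mapped to unknown ROIs: {sorted(missing)}")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[1]


def minimum_norm_operator(leadfield: LeadField, lam: float = 0.1,
                          standardize: bool = True) -> np.ndarray:
    """Tikhonov-regularized minimum-norm kernel with sLORETA standardization.

    Parameters
    ----------
    leadfield:
        Forward model ``L`` (sensors x voxels).
    lam:
        Relative regularization: the absolute Tikhonov parameter is
        ``lam`` times the mean eigenvalue of ``L L^T``.  ``lam = 0`` is
        allowed only for numerically full-rank sensor Gram matrices.

    Returns
    -------
    Operator ``W`` of shape (voxels x sensors); ``W @ y`` is the
    standardized current-density estimate for sensor vector ``y``.
    """
    if lam < 0:
        raise ValueError("regularization must be >= 0")
    L = leadfield.gain
    m = L.shape[0]
    gram = L @ L.T
    mean_eig = np.trace(gram) / m
    reg = lam * mean_eig
    if reg == 0.0:
        # unregularized: Moore-Penrose; voxels must be distinguishable
        if np.linalg.matrix_rank(L) < L.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient lead field: lam = 0 cannot separate voxels"
            )
        kernel = L.T @ np.linalg.pinv(gram)                # voxels x sensors
    else:
        kernel = L.T @ np.linalg.inv(gram + reg * np.eye(m))
    if not standardize:
        return kernel
    # resolution matrix diagonal: R = kernel @ L
    res_diag = np.einsum("vs,sv->v", kernel, L)
    if np.any(res_diag <= 0):
        raise np.linalg.LinAlgError("non-positive resolution diagonal")
    return kernel / np.sqrt(res_diag)[:, None]


def roi_timeseries(
    sensor_epochs: EpochSet,
    operator: np.ndarray,
    voxel_roi_map: Sequence[str],
    roi_labels: Sequence[str] | None = None,
) -> EpochSet:
    """Project sensor epochs to voxels and average voxels within each ROI."""
    operator = np.asarray(operator, dtype=float)
    if operator.shape[1] != sensor_epochs.n_channels:
        raise ValueError(
            f"operator expects {operator.shape[1]} sensors, "
            f"epochs have {sensor_epochs.n_channels}"
        )
    if operator.shape[0] != len(voxel_roi_map):
        raise ValueError("operator rows inconsistent with voxel_roi_map")
    voxel_roi_map = list(voxel_roi_map)
    if roi_labels is None:
        seen: dict[str, None] = {}
        for r in voxel_roi_map:
            seen.setdefault(r, None)
        roi_labels = list(seen)
    membership = {lab: [i for i, r in enumerate(voxel_roi_map) if r == lab]
                  for lab in roi_labels}
    for lab, idx in membership.items():
        if not idx:
            raise ValueError(f"ROI {lab!r} has no voxels")
    # averaging matrix (rois x voxels), then fold into the operator
    A = np.zeros((len(roi_labels), operator.shape[0]))
    for k, lab in enumerate(roi_labels):
        idx = membership[lab]
        A[k, idx] = 1.0 / len(idx)
    roi_op = A @ operator                               # rois x sensors
    data = np.tensordot(sensor_epochs.data, roi_op, axes=([1], [1]))
    data = np.moveaxis(data, -1, 1)                      # (epochs, rois, samples)
    return EpochSet(
        data=data,
        fs=sensor_epochs.fs,
        labels=list(roi_labels),
        subject=sensor_epochs.subject,
        condition=sensor_epochs.condition,
        meta={**sensor_epochs.meta, "space": "roi"},
    )
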