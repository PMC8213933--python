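"""Per-subject series -> single volumes x voxels analysis matrix.

Censoring, per-voxel temporal z-normalization, masking and stacking with
row-level provenance.  The resulting :class:`VolumeMatrix` is the substrate
of the clustering stage: each retained fMRI volume becomes one row whose
entries are that volume's in-mask voxel values after the voxel's time series
(censored volumes excluded) has been centred and scaled to unit SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectSeries",
    "VolumeMatrix",
    "temporal_normalize",
    "apply_mask_and_stack",
    "build_volume_matrix",
]

#: linearization convention for mask voxels: Fortran order on (x, y, z)
#: arrays, i.e. the x index varies fastest.
FLAT_ORDER = "F"


@dataclass
class SubjectSeries:
    """One subject's 4D BOLD array with its censor vector."""

    data: np.ndarray            # (x, y, z, t)
    subject_id: str
    group: str                  # 'A' or 'B'
    censor: np.ndarray          # (t,) bool, True = drop

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.censor = np.asarray(self.censor, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"subject {self.subject_id}: data must be 4D")
        if self.censor.shape != (self.data.shape[3],):
            raise ValueError(f"subject {self.subject_id}: censor length mismatch")


@dataclass
class VolumeMatrix:
    """N retained volumes x V in-mask voxels, z-normalized, with provenance."""

    values: np.ndarray          # (N, V) float
    provenance: pd.DataFrame    # columns: subject_id, group, volume_index
    mask: np.ndarray            # 3D bool with V true voxels
    flat_order: str = FLAT_ORDER

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def unflatten(self, vec: np.ndarray, fill=0.0) -> np.ndarray:
        """Place a V-vector back onto the 3D grid (fill outside the mask)."""
        out = np.full(self.mask.shape, fill, dtype=float)
        flat = out.ravel(order=self.flat_order)
        flat[self.mask.ravel(order=self.flat_order)] = vec
        return flat.reshape(self.mask.shape, order=self.flat_order)

    def validate(self) -> None:
        if self.values.shape[0] != len(self.provenance):
            raise ValueError("provenance rows != matrix rows")
        if self.values.shape[1] != int(self.mask.sum()):
            raise ValueError("matrix columns != in-mask voxel count")


def temporal_normalize(data: np.ndarray, censor: np.ndarray | None = None,
                       ddof: int = 1):
    """Z-normalize each voxel's time series over retained volumes.

    Per voxel, over non-censored volumes only: subtract the mean, divide by
    the temporal SD (sample SD, ``n-1`` denominator by default; ``ddof=0``
    gives the population SD).  Zero-variance voxels are set to 0 and flagged.
    Censored volumes are excluded both from the statistics and from the
    output.

    Returns ``(normalized, zero_variance)`` where ``normalized`` has shape
    ``(x, y, z, t_retained)`` and ``zero_variance`` is a 3D boolean flag map.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4D (x, y, z, t)")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in input series")
    t = data.shape[3]
    if censor is None:
        censor = np.zeros(t, dtype=bool)
    censor = np.asarray(censor, dtype=bool)
    retained = ~censor
    n_ret = int(retained.sum())
    if n_ret == 0:
        raise ValueError("all volumes censored")
    if n_ret < 2:
        raise ValueError("fewer than 2 retained volumes; cannot normalize")
    kept = data[..., retained]
    mean = kept.mean(axis=3, keepdims=True)
    sd = kept.std(axis=3, ddof=ddof, keepdims=True)
    # voxels whose temporal SD is at rounding-noise level relative to their
    # magnitude are physically constant; normalizing them would amplify
    # floating-point jitter to O(1)
    scale = np.abs(kept).max(axis=3, keepdims=True)
    zero_var = (sd <= 1e-8 * scale)[..., 0]
    sd_safe = np.where(zero_var[..., None], 1.0, sd)
    out = (kept - mean) / sd_safe
    out[zero_var, :] = 0.0
    return out, zero_var


def apply_mask_and_stack(series_list: list[SubjectSeries], mask: np.ndarray,
                         *, normalized: list[np.ndarray] | None = None,
                         ddof: int = 1) -> VolumeMatrix:
    """Mask, flatten and stack normalized subject series into a VolumeMatrix.

    Rows are ordered by (subject order given, retained volume time order);
    columns follow the x-fastest linearization of the mask.  When
    ``normalized`` is None each subject is temporally normalized here first.
    """
    mask = np.asarray(mask, dtype=bool)
    blocks, prov = [], []
    for i, s in enumerate(series_list):
        if s.data.shape[:3] != mask.shape:
            raise ValueError(
                f"subject {s.subject_id}: grid {s.data.shape[:3]} does not "
                f"match mask {mask.shape}"
            )
        if normalized is not None:
            norm = normalized[i]
        else:
            norm, _ = temporal_normalize(s.data, s.censor, ddof=ddof)
        t_ret = norm.shape[3]
        flat_mask = mask.ravel(order=FLAT_ORDER)
        # (t_ret, V): flatten each retained volume in x-fastest order
        vol2d = norm.reshape(-1, t_ret, order=FLAT_ORDER)[flat_mask].T
        blocks.append(vol2d)
        kept_idx = np.flatnonzero(~s.censor)
        if len(kept_idx) != t_ret:
            raise ValueError(
                f"subject {s.subject_id}: normalized series has {t_ret} "
                f"volumes but censor vector retains {len(kept_idx)}"
            )
        for v in kept_idx:
            prov.append((s.subject_id, s.group, int(v)))
    values = np.vstack(blocks)
    provenance = pd.DataFrame(prov, columns=["subject_id", "group", "volume_index"])
    vm = VolumeMatrix(values=values, provenance=provenance, mask=mask)
    vm.validate()
    return vm


def build_volume_matrix(dataset, ddof: int = 1) -> VolumeMatrix:
    """Convenience path from a synthetic dataset (or the dict returned by
    :func:`caphier.synthetic.read_dataset`) to a normalized VolumeMatrix."""
    if isinstance(dataset, dict):
        ids = dataset["subject_ids"]
        groups = dataset["group_labels"]
        series = dataset["series"]
        censors = dataset["censor_masks"]
        mask = dataset["mask"]
    else:
        ids, groups = dataset.subject_ids, dataset.group_labels
        series, censors, mask = dataset.series, dataset.censor_masks, dataset.mask
    subjects = [
        SubjectSeries(data=d, subject_id=i, group=g, censor=c)
        for d, i, g, c in zip(series, ids, groups, censors)
    ]
    return apply_mask_and_stack(subjects, mask, ddof=ddof)
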