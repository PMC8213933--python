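"""CAP z-statistic maps: aggregate member volumes into mean, SE and z = mean/SE.

The z map quantifies, per voxel, how strongly the CAP's member volumes
deviate from the (normalized) zero baseline: mean over members divided by the
standard error of that mean (within-cluster, across volumes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["CapZMap", "compute_cap_zmap", "compute_cap_zmaps", "export_zmap"]


@dataclass
class CapZMap:
    cap_label: str
    n_members: int
    mean: np.ndarray         # (V,)
    se: np.ndarray           # (V,)
    z: np.ndarray            # (V,), NaN where undefined
    undefined: np.ndarray    # (V,) bool: se == 0 or n_members < 2


def compute_cap_zmap(values, member_rows, cap_label: str = "",
                     ddof: int = 1) -> CapZMap:
    """Mean, SE and z over the member volumes of one CAP.

    ``se = sd / sqrt(n)`` with the sample SD (``ddof=1``) by default.
    Singleton CAPs and zero-SE voxels are flagged undefined rather than
    raising — singletons legitimately occur high in the hierarchy.
    """
    X = np.asarray(getattr(values, "values", values), dtype=float)
    member_rows = np.asarray(member_rows, dtype=int)
    if member_rows.size == 0:
        raise ValueError(f"CAP {cap_label or '<unnamed>'}: empty member set")
    M = X[member_rows]
    n = M.shape[0]
    mean = M.mean(axis=0)
    if n < 2:
        se = np.zeros_like(mean)
        undefined = np.ones_like(mean, dtype=bool)
    else:
        se = M.std(axis=0, ddof=ddof) / np.sqrt(n)
        undefined = se == 0
    z = np.full_like(mean, np.nan)
    ok = ~undefined
    z[ok] = mean[ok] / se[ok]
    return CapZMap(cap_label=cap_label, n_members=n, mean=mean, se=se,
                   z=z, undefined=undefined)


def compute_cap_zmaps(volume_matrix, labeling, ddof: int = 1) -> dict[str, CapZMap]:
    """Z maps for every unique CAP in a labeling (keyed by first label)."""
    return {
        lab: compute_cap_zmap(volume_matrix, members, cap_label=lab, ddof=ddof)
        for lab, members in labeling.unique_caps.items()
    }


def export_zmap(zmap: CapZMap, mask: np.ndarray, path, reference=None,
                flat_order: str = "F"):
    """Write a CAP z map as a 3D NIfTI-1 image.

    In-mask voxels carry z (NaN where flagged undefined), out-of-mask voxels
    are 0.  Affine and header are copied from ``reference`` (a nibabel image)
    when given.  Values are stored as float64 so a write/read round-trip is
    bit-exact.
    """
    import nibabel as nib

    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) != zmap.z.shape[0]:
        raise ValueError(
            f"mask has {int(mask.sum())} voxels but z vector has {zmap.z.shape[0]}"
        )
    vol = np.zeros(mask.shape, dtype=np.float64)
    flat = vol.ravel(order=flat_order)
    flat[mask.ravel(order=flat_order)] = zmap.z
    vol = flat.reshape(mask.shape, order=flat_order)
    if reference is not None and tuple(reference.shape[:3]) != mask.shape:
        raise ValueError(
            f"reference geometry {tuple(reference.shape[:3])} does not match "
            f"mask {mask.shape}"
        )
    if reference is not None:
        img = nib.Nifti1Image(vol, reference.affine, header=reference.header.copy())
        img.header.set_data_dtype(np.float64)
    else:
        img = nib.Nifti1Image(vol, np.eye(4))
        img.header.set_data_dtype(np.float64)
    nib.save(img, Path(path))
    return Path(path)
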