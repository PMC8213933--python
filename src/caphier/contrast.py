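"""Voxel-wise two-group comparison within each CAP.

The observed statistic is a pooled-variance two-sample t over each CAP's
member volumes.  Because volumes of one subject are not exchangeable with
another subject's volumes, the null distribution is built by permuting group
labels at the subject level: all volumes of a subject travel together
(subjects are the exchangeability blocks).  Optionally the t map is passed
through threshold-free cluster enhancement (TFCE) and the permuted TFCE value
at each voxel forms that voxel's null.  Uncorrected p maps from every
CAP x direction contrast are pooled and Benjamini-Hochberg corrected at a
single FDR level q.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DesignMatrix",
    "PermTTestResult",
    "PooledFdrResult",
    "build_design",
    "permutation_ttest",
    "tfce",
    "pooled_fdr",
    "two_tailed_threshold",
    "run_level_contrasts",
]

log = logging.getLogger(__name__)

# cap applied to non-finite t values (perfect separation) before TFCE
_T_CAP = 1e10


@dataclass
class DesignMatrix:
    """Volumes x (CAP x group) one-hot design at one hierarchy level."""

    matrix: np.ndarray                    # (N, 2L) uint8
    columns: list[tuple[str, str]]        # (cap_label, group) per column
    cap_members: dict[str, np.ndarray]    # cap_label -> member row indices
    skipped: list[str]                    # caps missing one group entirely

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def build_design(labeling, level: int, provenance) -> DesignMatrix:
    """One-hot CAP x group design for one level's partition.

    Every volume row activates exactly one of the ``2 * level`` cells.  CAPs
    in which one group has no volumes are excluded from contrasting (listed
    in ``skipped``, with a warning).
    """
    labels = labeling.labels_at(level)
    groups = provenance["group"].to_numpy()
    names = ["A", "B"] if set(groups) <= {"A", "B"} else sorted(set(groups))
    n = labels.shape[0]
    cols, mats, cap_members, skipped = [], [], {}, []
    for o in range(1, level + 1):
        lab = labeling.cap_label(level, o)
        members = np.flatnonzero(labels == o)
        cap_members[lab] = members
        per_group = []
        for g in names:
            col = ((labels == o) & (groups == g)).astype(np.uint8)
            per_group.append(col)
        if any(c.sum() == 0 for c in per_group):
            skipped.append(lab)
            warnings.warn(f"CAP {lab}: one group contributes no volumes; "
                          "contrast skipped")
        for g, col in zip(names, per_group):
            cols.append((lab, g))
            mats.append(col)
    return DesignMatrix(
        matrix=np.stack(mats, axis=1),
        columns=cols,
        cap_members=cap_members,
        skipped=skipped,
    )


def tfce(stat_map: np.ndarray, E: float = 0.5, H: float = 2.0,
         dh: float | None = None, connectivity: int = 26) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a 3D map.

    ``TFCE(v) = sum_{h=dh..max, step dh} e(v, h)^E * h^H * dh`` where
    ``e(v, h)`` is the voxel count of the connected component containing v at
    threshold h.  Defaults E=0.5, H=2, 26-connectivity, dh = max/100 (the
    standard parameters of the method).  Negative values are ignored — each
    contrast direction is enhanced separately on its own sign-flipped map.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.ndim != 3:
        raise ValueError("TFCE expects a 3D statistic map")
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("TFCE requires a finite map")
    pos = np.where(stat_map > 0, stat_map, 0.0)
    m = float(pos.max())
    out = np.zeros_like(pos)
    if m <= 0:
        return out
    if dh is None:
        dh = m / 100.0
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    n_steps = max(1, int(round(m / dh)))
    # thresholds dh, 2dh, ..., ~max; a hair of tolerance keeps the peak voxel
    # inside the top threshold despite float rounding
    for i in range(1, n_steps + 1):
        h = i * dh
        above = pos >= h * (1.0 - 1e-12)
        if not above.any():
            break
        lab, _ = ndimage.label(above, structure=structure)
        sizes = np.bincount(lab.ravel())
        extent = sizes[lab]
        out[above] += extent[above] ** E * h ** H * dh
    return out


@dataclass
class PermTTestResult:
    cap_label: str
    t: np.ndarray                 # (V,) observed pooled-variance t (A - B)
    p: dict[str, np.ndarray]      # direction -> (V,) permutation p
    tfce_obs: dict[str, np.ndarray] | None   # direction -> enhanced map (V,)
    n_perm_used: int
    exhaustive: bool
    directions: tuple[str, str] = ("A>B", "B>A")


def _group_stats(perm_is_a, c, S, Q):
    """Pooled-variance t for a batch of subject->group assignments.

    perm_is_a: (P, S) bool; c/S/Q: per-subject member-volume counts, sums and
    sums of squares, shapes (S,), (S, V), (S, V).  Returns (P, V) t values
    (NaN where undefined).
    """
    nA = perm_is_a @ c                       # (P,)
    nB = c.sum() - nA
    sumA = perm_is_a @ S                     # (P, V)
    sumB = S.sum(axis=0)[None, :] - sumA
    sqA = perm_is_a @ Q
    sqB = Q.sum(axis=0)[None, :] - sqA
    with np.errstate(divide="ignore", invalid="ignore"):
        mA = sumA / nA[:, None]
        mB = sumB / nB[:, None]
        ssA = sqA - nA[:, None] * mA ** 2
        ssB = sqB - nB[:, None] * mB ** 2
        df = (nA + nB - 2)[:, None]
        sp2 = (ssA + ssB) / df
        sp2 = np.maximum(sp2, 0.0)
        t = (mA - mB) / np.sqrt(sp2 * (1.0 / nA[:, None] + 1.0 / nB[:, None]))
    bad = (nA < 2) | (nB < 2)
    t[bad] = np.nan
    return t


def permutation_ttest(values, member_rows, subject_ids, groups,
                      n_perm: int = 10_000, seed=None,
                      tfce_enabled: bool = False, mask: np.ndarray | None = None,
                      flat_order: str = "F",
                      tfce_params: dict | None = None,
                      cap_label: str = "") -> PermTTestResult:
    """Subject-block permutation two-sample t-test over one CAP's volumes.

    Parameters
    ----------
    values : (N, V) array or VolumeMatrix
    member_rows : row indices of the CAP's member volumes
    subject_ids : (N,) subject id per row
    groups : mapping subject id -> 'A'/'B'
    n_perm : requested permutations; when the number of distinct subject
        group assignments (minus the observed one) is smaller, all of them
        are enumerated instead
    tfce_enabled : enhance each direction's t map with TFCE before computing
        voxel-wise permutation p (requires ``mask`` for 3D geometry)
    """
    X = np.asarray(getattr(values, "values", values), dtype=float)
    subject_ids = np.asarray(subject_ids)
    member_rows = np.asarray(member_rows, dtype=int)
    if member_rows.size == 0:
        raise ValueError(f"CAP {cap_label}: empty member set")

    subjects = list(dict.fromkeys(subject_ids.tolist()))
    S_n = len(subjects)
    subj_index = {s: i for i, s in enumerate(subjects)}
    is_a_obs = np.array([groups[s] == "A" for s in subjects])
    n_a_subj = int(is_a_obs.sum())
    if n_a_subj < 2 or S_n - n_a_subj < 2:
        raise ValueError("both groups must contribute at least 2 subjects")

    # per-subject aggregates over this CAP's member volumes
    rows = member_rows
    row_subj = np.array([subj_index[s] for s in subject_ids[rows]])
    V = X.shape[1]
    c = np.bincount(row_subj, minlength=S_n).astype(float)
    Ssum = np.zeros((S_n, V))
    Qsum = np.zeros((S_n, V))
    Xm = X[rows]
    np.add.at(Ssum, row_subj, Xm)
    np.add.at(Qsum, row_subj, Xm ** 2)

    # the CAP needs >=2 subjects and >=2 volumes from each group
    if (c[is_a_obs] > 0).sum() < 2 or (c[~is_a_obs] > 0).sum() < 2:
        raise ValueError(
            f"CAP {cap_label}: both groups must contribute at least 2 subjects"
        )
    if c[is_a_obs].sum() < 2 or c[~is_a_obs].sum() < 2:
        raise ValueError(f"CAP {cap_label}: fewer than 2 volumes in a group")

    n_distinct = math.comb(S_n, n_a_subj)
    if n_distinct - 1 < 2:
        raise ValueError("fewer than 2 distinct subject-label permutations")
    exhaustive = (n_distinct - 1) <= n_perm
    if exhaustive:
        perms = []
        obs_set = frozenset(np.flatnonzero(is_a_obs).tolist())
        for comb in itertools.combinations(range(S_n), n_a_subj):
            if frozenset(comb) == obs_set:
                continue
            row = np.zeros(S_n, dtype=bool)
            row[list(comb)] = True
            perms.append(row)
        perm_is_a = np.array(perms)
        n_perm_used = perm_is_a.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perm_is_a = np.array([rng.permutation(is_a_obs) for _ in range(n_perm)])
        n_perm_used = n_perm

    t_obs = _group_stats(is_a_obs[None, :], c, Ssum, Qsum)[0]
    t_perm = _group_stats(perm_is_a, c, Ssum, Qsum)

    def _finite(t):
        return np.nan_to_num(t, nan=np.nan, posinf=_T_CAP, neginf=-_T_CAP)

    directions = ("A>B", "B>A")
    p: dict[str, np.ndarray] = {}
    tfce_obs: dict[str, np.ndarray] | None = None

    if tfce_enabled:
        if mask is None:
            raise ValueError("TFCE requires the 3D mask")
        mask = np.asarray(mask, dtype=bool)
        tp = dict(E=0.5, H=2.0, dh=None, connectivity=26)
        if tfce_params:
            tp.update(tfce_params)

        def _enhance(tvec):
            vol = np.zeros(mask.shape)
            flat = vol.ravel(order=flat_order)
            flat[mask.ravel(order=flat_order)] = np.nan_to_num(
                tvec, nan=0.0, posinf=_T_CAP, neginf=-_T_CAP)
            vol = flat.reshape(mask.shape, order=flat_order)
            enh = tfce(vol, **tp)
            return enh.ravel(order=flat_order)[mask.ravel(order=flat_order)]

        tfce_obs = {"A>B": _enhance(t_obs), "B>A": _enhance(-t_obs)}
        ge = {d: np.zeros(V) for d in directions}
        for j in range(n_perm_used):
            for d, sgn in (("A>B", 1.0), ("B>A", -1.0)):
                enh = _enhance(sgn * t_perm[j])
                ge[d] += enh >= tfce_obs[d]
        for d in directions:
            p[d] = (1.0 + ge[d]) / (1.0 + n_perm_used)
    else:
        tf = _finite(t_perm)
        to = _finite(t_obs)
        # undefined permuted stats count as >= observed (conservative)
        for d, sgn in (("A>B", 1.0), ("B>A", -1.0)):
            cmp = sgn * tf >= sgn * to[None, :]
            cmp |= np.isnan(tf)
            pv = (1.0 + cmp.sum(axis=0)) / (1.0 + n_perm_used)
            pv[np.isnan(to)] = 1.0   # 0/0 voxels: no evidence either way
            p[d] = pv

    return PermTTestResult(
        cap_label=cap_label, t=t_obs, p=p, tfce_obs=tfce_obs,
        n_perm_used=n_perm_used, exhaustive=exhaustive,
    )


@dataclass
class PooledFdrResult:
    fdr_threshold: float          # BH p cutoff over the pooled family
    per_tail_threshold: float     # halved cutoff for two-tailed reporting
    q: float
    n_tests: int
    masks: dict                   # same keys as the input p maps


def two_tailed_threshold(pooled_cutoff: float) -> float:
    """Per-tail reporting threshold implied by a pooled two-tailed cutoff."""
    return pooled_cutoff / 2.0


def pooled_fdr(p_maps: dict, q: float = 0.05, two_tailed: bool = False) -> PooledFdrResult:
    """Benjamini-Hochberg over the pooled p values of every contrast.

    ``p_maps`` maps a contrast key (e.g. ``(cap_label, direction)``) to its
    in-mask p vector.  The BH cutoff is the largest p(i) with
    p(i) <= i*q/m over the pooled, sorted family.  Masks threshold each map
    at the cutoff (both directions are already members of the pooled family);
    with ``two_tailed=True`` the halved per-tail threshold is used instead,
    mirroring the convention of reporting a pooled cutoff of e.g. .004 as
    two-tailed p < .002.
    """
    if not p_maps:
        raise ValueError("empty p-map pool")
    pooled = np.concatenate([np.asarray(v, dtype=float).ravel()
                             for v in p_maps.values()])
    m = pooled.size
    ps = np.sort(pooled)
    crit = (np.arange(1, m + 1) / m) * q
    ok = ps <= crit
    cutoff = float(ps[ok][-1]) if ok.any() else 0.0
    per_tail = two_tailed_threshold(cutoff)
    thr = per_tail if two_tailed else cutoff
    masks = {k: np.asarray(v) <= thr if cutoff > 0 else np.zeros_like(v, dtype=bool)
             for k, v in p_maps.items()}
    return PooledFdrResult(fdr_threshold=cutoff, per_tail_threshold=per_tail,
                           q=q, n_tests=m, masks=masks)


def run_level_contrasts(volume_matrix, labeling, levels, groups=None,
                        n_perm: int = 10_000, q: float = 0.05, seed=None,
                        tfce_enabled: bool = True,
                        tfce_params: dict | None = None) -> dict:
    """Permutation contrasts for every CAP at the given levels + pooled FDR.

    Returns ``{"results": {(cap, dir): PermTTestResult}, "p_maps": ...,
    "fdr": PooledFdrResult, "skipped": [...]}``.  Each CAP is tested once per
    direction; the pooled BH family is all in-mask voxels of all contrasts at
    all requested levels.
    """
    prov = volume_matrix.provenance
    if groups is None:
        groups = dict(zip(prov["subject_id"], prov["group"]))
    subject_ids = prov["subject_id"].to_numpy()
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    results, p_maps, skipped = {}, {}, []
    if isinstance(levels, int):
        levels = [levels]
    for L in levels:
        design = build_design(labeling, L, prov)
        for lab, members in design.cap_members.items():
            if lab in design.skipped:
                skipped.append(lab)
                continue
            child = ss.spawn(1)[0]
            try:
                res = permutation_ttest(
                    volume_matrix, members, subject_ids, groups,
                    n_perm=n_perm, seed=child, tfce_enabled=tfce_enabled,
                    mask=volume_matrix.mask, flat_order=volume_matrix.flat_order,
                    tfce_params=tfce_params, cap_label=lab,
                )
            except ValueError as e:
                log.warning("CAP %s skipped: %s", lab, e)
                skipped.append(lab)
                continue
            results[lab] = res
            for d in res.directions:
                p_maps[(lab, d)] = res.p[d]
    fdr = pooled_fdr(p_maps, q=q)
    log.info("pooled BH cutoff %.6g (per-tail %.6g) over %d tests",
             fdr.fdr_threshold, fdr.per_tail_threshold, fdr.n_tests)
    return {"results": results, "p_maps": p_maps, "fdr": fdr, "skipped": skipped}
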