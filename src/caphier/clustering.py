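"""Hierarchical co-activation pattern (CAP) extraction.

Pairwise cosine distances among all volumes are agglomerated with Ward's
method (ward.D2 semantics: Lance-Williams updates on squared dissimilarities,
heights reported on the original scale — the behaviour of R's
``hclust(method="ward.D2")``, which scipy's ``linkage(method="ward")``
reproduces on a precomputed condensed distance matrix).  The tree is cut at
every cluster count ("level") in a range, by default 2..30, and the distinct
member-sets across levels are registered as CAPs with "level-ordinal" labels
and parent/child (cladogram) relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "MergeTree",
    "CapLabeling",
    "cosine_distance_matrix",
    "ward_linkage",
    "cut_levels",
    "labeling_from_levels",
    "occupancy_split",
    "split_percentages",
    "CapWardClustering",
]


def cosine_distance_matrix(volume_matrix, block_rows: int = 1024) -> np.ndarray:
    """Full N x N cosine distance matrix, d = 1 - cos, range [0, 2].

    Accepts a :class:`~caphier.volume_prep.VolumeMatrix` or a plain (N, V)
    array.  The Gram product is evaluated in row blocks so the transient
    working memory beyond the N x N result stays bounded.  Rows with zero
    norm are rejected with an error that lists their provenance.
    """
    prov = getattr(volume_matrix, "provenance", None)
    X = np.asarray(getattr(volume_matrix, "values", volume_matrix), dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2D volumes x voxels matrix")
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        if prov is not None:
            who = ", ".join(
                f"({r.subject_id}, vol {r.volume_index})"
                for r in prov.iloc[bad[:10]].itertuples()
            )
        else:
            who = ", ".join(map(str, bad[:10]))
        raise ValueError(f"zero-norm volume rows cannot enter cosine distance: {who}")
    Xn = X / norms[:, None]
    n = X.shape[0]
    D = np.empty((n, n))
    for start in range(0, n, block_rows):
        stop = min(start + block_rows, n)
        D[start:stop] = 1.0 - Xn[start:stop] @ Xn.T
    D = 0.5 * (D + D.T)          # enforce exact symmetry
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class MergeTree:
    """Binary agglomeration tree in scipy linkage form.

    ``Z[i] = (child_a, child_b, height, size)`` with leaves 0..N-1 and
    internal node ``i`` numbered ``N + i``.  Ward heights are nondecreasing.
    """

    Z: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.Z.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return leaves_list(self.Z)


def ward_linkage(distance_matrix: np.ndarray) -> MergeTree:
    """Agglomerate a precomputed distance matrix under the ward.D2 criterion."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="ward")
    return MergeTree(Z=np.asarray(Z))


@dataclass
class CapLabeling:
    """CAP assignments for every cut level plus the deduplicated registry.

    ``levels[L]`` holds, per volume, the 1-based ordinal of its cluster at
    the cut producing exactly L clusters; ordinals follow the order of first
    appearance in dendrogram leaf order.  ``unique_caps`` maps each distinct
    member-set (as a sorted row-index tuple is too large; keyed by its label
    of first appearance) to its membership; ``first_label`` identifies
    member-sets that persist across several levels by the lowest level at
    which they occur.
    """

    n_volumes: int
    level_min: int
    level_max: int
    levels: dict[int, np.ndarray]                # L -> (N,) ordinals 1..L
    unique_caps: dict[str, np.ndarray]           # first label -> member row idx
    cap_level: dict[str, int]                    # first label -> level of first appearance
    label_alias: dict[str, str]                  # any level label -> first label
    parent_of: dict[str, str]                    # label at L -> label at L-1

    @property
    def n_unique_caps(self) -> int:
        return len(self.unique_caps)

    def cap_label(self, level: int, ordinal: int) -> str:
        return f"{level:02d}-{ordinal:02d}"

    def members(self, label: str) -> np.ndarray:
        """Member row indices of a CAP given any of its level labels."""
        return self.unique_caps[self.label_alias[label]]

    def labels_at(self, level: int) -> np.ndarray:
        return self.levels[level]


def _cluster_members_at_levels(Z: np.ndarray, level_min: int, level_max: int):
    """Member lists of the active clusters at each cut level.

    Cutting a binary tree with N leaves after ``N - L`` merges leaves exactly
    L active nodes.  Implemented as a single union-find sweep over the merge
    sequence with partition snapshots at the requested levels, so memory
    stays O(N) regardless of tree shape.
    """
    n = Z.shape[0] + 1
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out: dict[int, list[np.ndarray]] = {}
    want = {n - L: L for L in range(level_min, level_max + 1)}
    last_merge = n - level_min
    for m in range(last_merge + 1):
        if m in want:
            roots = np.fromiter((find(v) for v in range(n)), dtype=np.int64, count=n)
            order = np.argsort(roots, kind="stable")
            bounds = np.flatnonzero(np.diff(roots[order])) + 1
            out[want[m]] = [np.sort(g) for g in np.split(order, bounds)]
        if m < last_merge:
            a, b = int(Z[m, 0]), int(Z[m, 1])
            node = n + m
            parent[find(a)] = node
            parent[find(b)] = node
    return out


def cut_levels(tree: MergeTree, level_min: int = 2, level_max: int = 30) -> CapLabeling:
    """Cut the merge tree at every level in ``[level_min, level_max]``.

    At each level the cut produces exactly L clusters; ordinals within a
    level follow the order of first member appearance in dendrogram leaf
    order.  Identical member-sets recurring at several levels are
    deduplicated in the CAP registry (a binary tree over levels ``a..b`` with
    distinct heights yields ``2 + 2*(b - a)`` distinct CAPs).  ``parent_of``
    links each level-L CAP label to the level-(L-1) label whose member-set
    contains it.
    """
    Z = tree.Z
    n = tree.n_leaves
    if level_min < 1:
        raise ValueError("level_min must be >= 1")
    if level_max > n:
        raise ValueError(f"level_max={level_max} exceeds volume count N={n}")
    if level_min > level_max:
        raise ValueError("level_min must be <= level_max")

    leaf_pos = np.empty(n, dtype=int)
    leaf_pos[tree.leaf_order] = np.arange(n)

    per_level = _cluster_members_at_levels(Z, level_min, level_max)
    levels: dict[int, np.ndarray] = {}
    for L in range(level_min, level_max + 1):
        clusters = per_level[L]
        # order clusters by first appearance in leaf order
        firsts = [leaf_pos[m].min() for m in clusters]
        order = np.argsort(firsts)
        labels = np.empty(n, dtype=int)
        for ordinal, ci in enumerate(order, start=1):
            labels[clusters[ci]] = ordinal
        levels[L] = labels
    return labeling_from_levels(levels)


def labeling_from_levels(levels: dict[int, np.ndarray]) -> CapLabeling:
    """Assemble a :class:`CapLabeling` from per-level ordinal assignments.

    Deduplicates member-sets across levels into the CAP registry and derives
    parent/child (cladogram) links.  Also the reconstruction path when a
    labeling is read back from its TSV serialization.
    """
    lvls = sorted(levels)
    level_min, level_max = lvls[0], lvls[-1]
    n = len(levels[level_min])
    unique_caps: dict[str, np.ndarray] = {}
    cap_level: dict[str, int] = {}
    label_alias: dict[str, str] = {}
    parent_of: dict[str, str] = {}
    set_to_first: dict[frozenset, str] = {}
    for L in lvls:
        labels = np.asarray(levels[L])
        ordinals = np.unique(labels)
        if len(ordinals) != L or labels.shape[0] != n:
            raise ValueError(f"level {L}: expected a partition into {L} clusters")
        for o in ordinals:
            lab = f"{L:02d}-{int(o):02d}"
            members = np.flatnonzero(labels == o)
            fs = frozenset(members.tolist())
            first = set_to_first.get(fs)
            if first is None:
                unique_caps[lab] = members
                cap_level[lab] = L
                set_to_first[fs] = lab
                first = lab
            label_alias[lab] = first
            if L > level_min and (L - 1) in levels:
                rep = int(members[0])
                po = int(levels[L - 1][rep])
                parent_of[lab] = f"{L - 1:02d}-{po:02d}"
    return CapLabeling(
        n_volumes=n,
        level_min=level_min,
        level_max=level_max,
        levels={L: np.asarray(levels[L]) for L in lvls},
        unique_caps=unique_caps,
        cap_level=cap_level,
        label_alias=label_alias,
        parent_of=parent_of,
    )


def split_percentages(counts) -> np.ndarray:
    """Integer-rounded percentage split of a count vector (reporting rule)."""
    counts = np.asarray(counts, dtype=float)
    return np.rint(100.0 * counts / counts.sum()).astype(int)


def occupancy_split(labeling: CapLabeling, level: int) -> pd.DataFrame:
    """Per-CAP volume counts, fractions and rounded percentages at one level."""
    labels = labeling.labels_at(level)
    n = labeling.n_volumes
    rows = []
    counts = np.array([(labels == o).sum() for o in range(1, level + 1)])
    pcts = split_percentages(counts)
    for o in range(1, level + 1):
        rows.append((labeling.cap_label(level, o), int(counts[o - 1]),
                     counts[o - 1] / n, int(pcts[o - 1])))
    return pd.DataFrame(rows, columns=["cap_label", "count", "fraction", "percent"])


class CapWardClustering(ClusterMixin, BaseEstimator):
    """Cosine-distance Ward clustering of fMRI volumes, sklearn style.

    ``fit(X)`` computes the full cosine distance matrix of the rows of X,
    agglomerates with ward.D2 semantics and cuts the tree at every level in
    ``[level_min, level_max]``.  ``labels_`` holds the 0-based cluster
    assignment at ``level``; the full multi-level labeling and the merge tree
    are exposed as ``labeling_`` and ``tree_``.

    Parameters
    ----------
    level : int, default 2
        Cut level whose assignment populates ``labels_``.
    level_min, level_max : int
        Range of cut levels to enumerate (CAP registry).  ``level_max`` is
        clipped to the number of samples at fit time when larger.
    block_rows : int
        Row-block size of the distance computation (memory bound).
    """

    def __init__(self, level: int = 2, level_min: int = 2, level_max: int = 30,
                 block_rows: int = 1024):
        self.level = level
        self.level_min = level_min
        self.level_max = level_max
        self.block_rows = block_rows

    def fit(self, X, y=None):
        values = X.values if hasattr(X, "values") and hasattr(X, "provenance") else X
        values = check_array(values, dtype=float)
        n = values.shape[0]
        if not (self.level_min <= self.level <= self.level_max):
            raise ValueError("level must lie within [level_min, level_max]")
        if self.level_max > n:
            raise ValueError(f"level_max={self.level_max} exceeds n_samples={n}")
        D = cosine_distance_matrix(X if hasattr(X, "provenance") else values,
                                   block_rows=self.block_rows)
        self.tree_ = ward_linkage(D)
        self.labeling_ = cut_levels(self.tree_, self.level_min, self.level_max)
        self.labels_ = self.labeling_.labels_at(self.level) - 1
        self.n_features_in_ = values.shape[1]
        return self

    def labels_at(self, level: int) -> np.ndarray:
        check_is_fitted(self, "labeling_")
        return self.labeling_.labels_at(level) - 1
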