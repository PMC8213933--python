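"""Per-subject CAP occupancy and its group comparison.

Occupancy is the number of a subject's retained volumes assigned to a CAP.
Groups are compared per CAP with medians + percentile-bootstrap confidence
intervals and two-sided Mann-Whitney tests, Benjamini-Hochberg corrected
across the whole CAP family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OccupancyTable",
    "occupancy_table",
    "group_median_ci",
    "mannwhitney_fdr",
]

# exact Mann-Whitney enumeration is used when both groups are at most this size
EXACT_MW_MAX_N = 8


@dataclass
class OccupancyTable:
    counts: pd.DataFrame          # subjects x CAP labels (integer volumes)
    groups: pd.Series             # subject -> 'A'/'B'
    retained_total: pd.Series     # subject -> retained volume count
    cap_level: dict[str, int]     # CAP label -> level of first appearance

    def fractions(self) -> pd.DataFrame:
        """Counts normalized by each subject's retained volume total."""
        return self.counts.div(self.retained_total, axis=0)

    def validate(self) -> None:
        # row sums are only meaningful within one level's partition; callers
        # check those via `level_row_sums`
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative occupancy count")


def occupancy_table(labeling, provenance: pd.DataFrame,
                    groups: dict[str, str] | pd.Series | None = None) -> OccupancyTable:
    """Tabulate volumes per subject per unique CAP.

    ``provenance`` is the VolumeMatrix row table (subject_id, group,
    volume_index); ``groups`` may override the group column.  Counts are
    exact; within any single level the per-subject counts over that level's
    CAPs sum to the subject's retained total.
    """
    if len(provenance) != labeling.n_volumes:
        raise ValueError("provenance does not cover all volume rows")
    subj = provenance["subject_id"].to_numpy()
    subjects = list(pd.unique(subj))
    if groups is None:
        gmap = (provenance.drop_duplicates("subject_id")
                .set_index("subject_id")["group"])
    else:
        gmap = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        missing = [s for s in subjects if s not in gmap.index]
        if missing:
            raise ValueError(f"unknown subjects in provenance: {missing}")
    counts = {}
    for lab, members in labeling.unique_caps.items():
        vc = pd.Series(subj[members]).value_counts()
        counts[lab] = vc
    table = (pd.DataFrame(counts).reindex(subjects).fillna(0).astype(int))
    retained = pd.Series(subj).value_counts().reindex(subjects)
    out = OccupancyTable(
        counts=table,
        groups=gmap.reindex(subjects),
        retained_total=retained,
        cap_level=dict(labeling.cap_level),
    )
    out.validate()
    return out


def level_row_sums(table: OccupancyTable, labeling, level: int) -> pd.Series:
    """Per-subject volume total over the CAPs forming one level's partition."""
    labs = [labeling.label_alias[f"{level:02d}-{o:02d}"] for o in range(1, level + 1)]
    return table.counts[labs].sum(axis=1)


def group_median_ci(counts, groups, n_boot: int = 10_000, level: float = 0.95,
                    seed=None) -> dict[str, tuple[float, float, float]]:
    """Group medians with percentile-bootstrap CIs (subjects resampled with
    replacement within group).  Returns {group: (median, lo, hi)}."""
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    if counts.size == 0:
        raise ValueError("empty group: no subjects to resample")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    out = {}
    for g in pd.unique(groups):
        x = counts[groups == g]
        if x.size == 0:
            raise ValueError(f"group {g!r} is empty")
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        boot = np.median(x[idx], axis=1)
        out[str(g)] = (
            float(np.median(x)),
            float(np.quantile(boot, alpha)),
            float(np.quantile(boot, 1.0 - alpha)),
        )
    return out


def mannwhitney_fdr(table: OccupancyTable, caps: list[str] | None = None,
                    q: float = 0.05, use_fractions: bool = False) -> pd.DataFrame:
    """Two-sided Mann-Whitney per CAP with BH FDR across all tested CAPs.

    The exact null distribution is enumerated when both groups have at most
    8 subjects; otherwise the tie-corrected normal approximation is used.
    Constant data in both groups yields p = 1 with a warning.
    """
    data = table.fractions() if use_fractions else table.counts
    caps = list(data.columns) if caps is None else caps
    g = table.groups.to_numpy()
    names = pd.unique(g)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    a_idx, b_idx = g == names[0], g == names[1]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    pvals = []
    for cap in caps:
        x = data[cap].to_numpy()[a_idx]
        y = data[cap].to_numpy()[b_idx]
        if np.ptp(np.concatenate([x, y])) == 0:
            warnings.warn(f"CAP {cap}: constant occupancy in both groups; p = 1")
            pvals.append(1.0)
            continue
        method = ("exact" if (x.size <= EXACT_MW_MAX_N and y.size <= EXACT_MW_MAX_N)
                  else "asymptotic")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        pvals.append(float(min(res.pvalue, 1.0)))
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return pd.DataFrame({
        "cap_label": caps,
        "level": [table.cap_level.get(c) for c in caps],
        "p_raw": pvals,
        "p_fdr": p_adj,
        "significant": reject,
    })
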