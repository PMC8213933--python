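"""Synthetic multi-subject resting-state fMRI generator with known latent brain states.

Each subject's 4D series is a noisy linear mixture of K smooth network maps
whose signed amplitudes are driven by a two-state latent Markov chain
("macro-states": a default-mode-positive and a default-mode-negative state),
optionally refined into sub-states with distinct amplitude rows.  A group
effect (reduced deactivation in selected networks during a designated
macro-state) and i.i.d. Bernoulli volume censoring complete the emulation of
a two-group resting-state study.  Everything downstream of the generator can
therefore be validated against exact ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "default_amplitude_table",
    "make_network_maps",
    "simulate_state_sequence",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "study_preset",
    "effect_preset",
    "null_preset",
]

# Map value below which a blob no longer contributes to the analysis mask.
# Network atlases in this pipeline are thresholded cores, conventionally cut
# around z ~ 3.5 against peaks over ~14, i.e. about a quarter of the peak;
# the synthetic blobs (peak 1) use the same relative cut.
SUPPORT_THRESHOLD = 0.25


def default_amplitude_table(n_networks: int, substates_per_macro: int,
                            base: float = 1.0) -> np.ndarray:
    """Signed network amplitudes per latent sub-state, shape (K, 2*P).

    Column ``macro * P + sub`` holds the amplitudes of sub-state ``sub`` of
    macro-state ``macro``.  The first ``ceil(K/2)`` networks behave like the
    default-mode complex (positive in macro 0, negative in macro 1); the rest
    behave like task-positive networks (opposite signs).  Sub-state ``j``
    scales all amplitudes by ``1 + 0.25*j`` so that amplitude rows are
    pairwise distinct, which makes sub-states separable in the noiseless
    limit.
    """
    K, P = n_networks, substates_per_macro
    dmn = np.arange(K) < (K + 1) // 2
    sign = np.where(dmn[:, None], [1.0, -1.0], [-1.0, 1.0])  # (K, 2)
    # alternate the sub-state modulation sign across networks so sub-state
    # amplitude rows are not collinear (cosine distance must separate them)
    alt = np.where(np.arange(K) % 2 == 0, 1.0, -1.0)
    table = np.empty((K, 2 * P))
    for macro in range(2):
        for sub in range(P):
            table[:, macro * P + sub] = sign[:, macro] * base * (1 + 0.25 * sub * alt)
    return table


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults emulate the target study design: two groups of 27 adolescents,
    250 volumes per subject before censoring, 14 network maps, ~13.2% of
    volumes censored, and unit-amplitude network signals in unit-SD noise.
    """

    seed: int = 0
    n_subjects_per_group: int = 27
    n_volumes: int = 250
    grid_shape: tuple[int, int, int] = (24, 24, 18)
    n_networks: int = 14
    macro_transition_prob: float = 0.1
    #: optional (p_leave_state0, p_leave_state1); overrides the symmetric
    #: chain to reproduce an asymmetric (e.g. 61/39) occupancy split.
    macro_switch_probs: tuple[float, float] | None = None
    substates_per_macro: int = 2
    amplitude_table: np.ndarray | None = None
    noise_sd: float = 1.0
    group_effect_delta: float = 0.0
    affected_networks: tuple[int, ...] = ()
    #: macro-state during which the group-B amplitude offset applies
    affected_macro: int = 1
    censor_fraction: float = 0.132
    blob_sigma: float = 2.0

    def resolved_amplitudes(self) -> np.ndarray:
        if self.amplitude_table is None:
            return default_amplitude_table(self.n_networks, self.substates_per_macro)
        return np.asarray(self.amplitude_table, dtype=float)

    def validate(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_volumes < 1:
            raise ValueError("subject and volume counts must be >= 1")
        if self.n_networks < 1 or self.substates_per_macro < 1:
            raise ValueError("n_networks and substates_per_macro must be >= 1")
        if not (0.0 < self.macro_transition_prob < 1.0):
            raise ValueError("macro_transition_prob must lie in (0, 1)")
        if self.macro_switch_probs is not None:
            if not all(0.0 < p < 1.0 for p in self.macro_switch_probs):
                raise ValueError("macro_switch_probs must lie in (0, 1)")
        if not (0.0 <= self.censor_fraction < 1.0):
            raise ValueError("censor_fraction must lie in [0, 1)")
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        amp = self.resolved_amplitudes()
        if not np.all(np.isfinite(amp)):
            raise ValueError("amplitude_table must be finite")
        if amp.shape != (self.n_networks, 2 * self.substates_per_macro):
            raise ValueError(
                f"amplitude_table shape {amp.shape} inconsistent with "
                f"(n_networks={self.n_networks}, "
                f"2*substates_per_macro={2 * self.substates_per_macro})"
            )
        if any(k < 0 or k >= self.n_networks for k in self.affected_networks):
            raise ValueError("affected_networks indices out of range")
        if self.affected_macro not in (0, 1):
            raise ValueError("affected_macro must be 0 or 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SynthDataset:
    """Generated dataset plus full ground truth."""

    config: SynthConfig
    subject_ids: list[str]
    group_labels: list[str]                 # 'A' or 'B' per subject
    series: list[np.ndarray]                # (x, y, z, t) float32 per subject
    mask: np.ndarray                        # 3D bool; union of map supports
    network_maps: np.ndarray                # (K, x, y, z), peak 1 each
    ownership: np.ndarray                   # 3D int, -1 = unassigned
    state_labels: list[np.ndarray]          # (t, 2) int: macro, sub
    censor_masks: list[np.ndarray]          # (t,) bool, True = censored

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def retained_counts(self) -> np.ndarray:
        return np.array([int((~c).sum()) for c in self.censor_masks])

    def retained_state_labels(self, s: int) -> np.ndarray:
        """State labels of subject *s* restricted to retained volumes."""
        return self.state_labels[s][~self.censor_masks[s]]


def make_network_maps(grid_shape, n_networks: int, seed,
                      sigma: float = 2.0, min_separation: float | None = None):
    """Place K isotropic Gaussian blobs on the grid.

    Returns ``(maps, ownership, mask)``: ``maps`` is (K, x, y, z) with each
    blob normalized to peak exactly 1 at its (integer-voxel) center;
    ``ownership`` assigns every in-mask voxel to the network with the largest
    map value (the generator's ground-truth atlas; -1 outside the mask);
    ``mask`` is the union of blob supports (map >= 0.05).

    Raises ``ValueError`` when K centers with the required pairwise
    separation cannot be placed on the grid.
    """
    rng = np.random.default_rng(seed)
    grid_shape = tuple(int(g) for g in grid_shape)
    if min_separation is None:
        # keep blob cores mostly disjoint so ownership is meaningful
        min_separation = max(2.0, 2.5 * sigma)
    margin = 2  # keep peaks off the grid boundary where possible
    lo = [min(margin, g - 1) for g in grid_shape]
    hi = [max(g - margin, l + 1) for g, l in zip(grid_shape, lo)]
    centers: list[np.ndarray] = []
    for _ in range(200):            # fresh restarts avoid dead-end layouts
        centers = []
        for _ in range(100 * n_networks):
            c = np.array([rng.integers(l, h) for l, h in zip(lo, hi)])
            if all(np.linalg.norm(c - c0) >= min_separation for c0 in centers):
                centers.append(c)
                if len(centers) == n_networks:
                    break
        if len(centers) == n_networks:
            break
    if len(centers) < n_networks:
        raise ValueError(
            f"grid {grid_shape} too small to place {n_networks} blob centers "
            f"with pairwise separation >= {min_separation:g} voxels"
        )
    xx, yy, zz = np.meshgrid(*(np.arange(g) for g in grid_shape), indexing="ij")
    maps = np.empty((n_networks,) + grid_shape)
    for k, c in enumerate(centers):
        d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        maps[k] = np.exp(-d2 / (2.0 * sigma ** 2))
    mask = (maps >= SUPPORT_THRESHOLD).any(axis=0)
    ownership = np.where(mask, np.argmax(maps, axis=0), -1)
    return maps, ownership, mask


def simulate_state_sequence(n_volumes: int, macro_transition_prob: float,
                            substates_per_macro: int, seed, *,
                            switch_probs: tuple[float, float] | None = None,
                            start: int | None = None) -> np.ndarray:
    """First-order Markov macro chain with uniform sub-state draws at dwell onsets.

    The macro chain is symmetric with stay probability
    ``1 - macro_transition_prob`` unless ``switch_probs`` gives per-state
    leave probabilities (the asymmetric preset).  The sub-state is redrawn
    uniformly whenever a new dwell starts and held constant within the dwell.
    Returns an ``(n_volumes, 2)`` integer array of (macro, sub) labels.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    if switch_probs is None:
        switch_probs = (macro_transition_prob, macro_transition_prob)
    p_leave = np.asarray(switch_probs, dtype=float)
    if start is None:
        # stationary start: pi_0 = p_leave[1] / (p_leave[0] + p_leave[1])
        pi0 = p_leave[1] / (p_leave[0] + p_leave[1])
        macro = int(rng.random() >= pi0)
    else:
        macro = int(start)
    P = substates_per_macro
    out = np.empty((n_volumes, 2), dtype=np.int64)
    sub = int(rng.integers(P))
    out[0] = (macro, sub)
    for t in range(1, n_volumes):
        if rng.random() < p_leave[macro]:
            macro = 1 - macro
            sub = int(rng.integers(P))
        out[t] = (macro, sub)
    return out


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Simulate the full multi-subject dataset described by *config*.

    Volume ``v`` of subject ``s`` is ``sum_k a_k(state, group) * map_k + eps``
    with ``eps ~ N(0, noise_sd^2)`` i.i.d. per voxel.  For group-B subjects
    the amplitude of each affected network is shifted by
    ``group_effect_delta`` whenever the affected macro-state is active
    (reduced deactivation when the base amplitude is negative).  Censored
    volumes are flagged, not removed.  The whole dataset is a deterministic
    function of ``config`` (including ``seed``).
    """
    config.validate()
    amp = config.resolved_amplitudes()
    ss = np.random.SeedSequence(config.seed)
    map_seed, *subject_seeds = ss.spawn(1 + 2 * config.n_subjects_per_group)
    maps, ownership, mask = make_network_maps(
        config.grid_shape, config.n_networks, map_seed, sigma=config.blob_sigma
    )

    n_total = 2 * config.n_subjects_per_group
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_total)]
    group_labels = ["A"] * config.n_subjects_per_group + ["B"] * config.n_subjects_per_group

    P = config.substates_per_macro
    series, state_labels, censor_masks = [], [], []
    for s in range(n_total):
        rng = np.random.default_rng(subject_seeds[s])
        states = simulate_state_sequence(
            config.n_volumes, config.macro_transition_prob, P, rng,
            switch_probs=config.macro_switch_probs,
        )
        a = amp[:, states[:, 0] * P + states[:, 1]].copy()  # (K, t)
        if group_labels[s] == "B" and config.group_effect_delta != 0.0:
            hit = states[:, 0] == config.affected_macro
            for k in config.affected_networks:
                a[k, hit] += config.group_effect_delta
        signal = np.tensordot(maps, a, axes=(0, 0))  # (x, y, z, t)
        data = signal.astype(np.float32)
        if config.noise_sd > 0:
            data = data + rng.normal(
                0.0, config.noise_sd, size=signal.shape
            ).astype(np.float32)
        censor = rng.random(config.n_volumes) < config.censor_fraction
        if (~censor).sum() < 2:
            raise ValueError(
                f"censoring left fewer than 2 volumes for subject {subject_ids[s]}"
            )
        series.append(data)
        state_labels.append(states)
        censor_masks.append(censor)

    return SynthDataset(
        config=config,
        subject_ids=subject_ids,
        group_labels=group_labels,
        series=series,
        mask=mask,
        network_maps=maps,
        ownership=ownership,
        state_labels=state_labels,
        censor_masks=censor_masks,
    )


# --------------------------------------------------------------------------
# presets

def study_preset(seed: int = 0, **overrides) -> SynthConfig:
    """Conditions mirroring the emulated study: 2x27 subjects, 250 volumes,
    14 networks, 13.2% censoring, asymmetric (61/39) macro occupancy."""
    cfg = SynthConfig(
        seed=seed,
        macro_switch_probs=(0.078, 0.122),  # 61% DMN-positive / 39% negative
    )
    return dataclasses.replace(cfg, **overrides)


def effect_preset(seed: int = 0, **overrides) -> SynthConfig:
    """Small power-analysis preset: 6+6 subjects, 100 volumes, 8 networks,
    reduced deactivation (delta = 1 noise SD) in 2 networks during the
    deactivation macro-state."""
    cfg = SynthConfig(
        seed=seed,
        n_subjects_per_group=6,
        n_volumes=100,
        grid_shape=(16, 16, 12),
        n_networks=8,
        group_effect_delta=1.0,
        affected_networks=(0, 1),
        affected_macro=1,
        censor_fraction=0.132,
    )
    return dataclasses.replace(cfg, **overrides)


def null_preset(seed: int = 0, **overrides) -> SynthConfig:
    """Effect-free twin of :func:`effect_preset` for calibration checks.

    Uses a single sub-state per macro-state so that, within a macro-state,
    the signal component of every volume is identical: under the null the
    only between-volume variation is i.i.d. measurement noise, which makes
    voxel-wise test statistics independent across voxels.
    """
    cfg = effect_preset(seed=seed)
    cfg = dataclasses.replace(
        cfg, group_effect_delta=0.0, affected_networks=(), substates_per_macro=1
    )
    return dataclasses.replace(cfg, **overrides)


# --------------------------------------------------------------------------
# disk round-trip (NIfTI-1 + TSV)

def write_dataset(ds: SynthDataset, outdir) -> list[Path]:
    """Write the dataset as per-subject NIfTI series, mask, atlas stack and
    ground-truth TSVs.  Returns the list of paths written."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    written: list[Path] = []

    def _save(img_data, name):
        p = outdir / name
        nib.save(nib.Nifti1Image(np.asarray(img_data), affine), p)
        written.append(p)
        return p

    _save(ds.mask.astype(np.uint8), "mask.nii")
    _save(np.moveaxis(ds.network_maps, 0, -1), "atlas.nii")
    _save(ds.ownership.astype(np.int16), "ownership.nii")
    for sid, data in zip(ds.subject_ids, ds.series):
        _save(data, f"{sid}_bold.nii")

    subjects = pd.DataFrame({"subject_id": ds.subject_ids, "group": ds.group_labels})
    p = outdir / "subjects.tsv"
    subjects.to_csv(p, sep="\t", index=False)
    written.append(p)

    rows = []
    for s, sid in enumerate(ds.subject_ids):
        st, cz = ds.state_labels[s], ds.censor_masks[s]
        for v in range(len(cz)):
            rows.append((sid, v, int(st[v, 0]), int(st[v, 1]), int(cz[v])))
    truth = pd.DataFrame(rows, columns=["subject_id", "volume_index",
                                        "macro", "sub", "censored"])
    p = outdir / "ground_truth.tsv"
    truth.to_csv(p, sep="\t", index=False)
    written.append(p)
    return written


def read_dataset(indir) -> dict:
    """Read back a directory written by :func:`write_dataset`.

    Returns a plain dict (not a :class:`SynthDataset`: the config is not
    serialized) with keys ``subject_ids, group_labels, series, mask,
    network_maps, ownership, censor_masks, state_labels``.
    """
    import nibabel as nib

    indir = Path(indir)
    subjects = pd.read_csv(indir / "subjects.tsv", sep="\t")
    truth = pd.read_csv(indir / "ground_truth.tsv", sep="\t")
    mask = np.asarray(nib.load(indir / "mask.nii").dataobj).astype(bool)
    atlas = np.asarray(nib.load(indir / "atlas.nii").dataobj)
    maps = np.moveaxis(atlas, -1, 0)
    ownership = np.asarray(nib.load(indir / "ownership.nii").dataobj).astype(int)
    series, censor_masks, state_labels = [], [], []
    for sid in subjects["subject_id"]:
        img = nib.load(indir / f"{sid}_bold.nii")
        series.append(np.asarray(img.dataobj))
        t = truth[truth["subject_id"] == sid].sort_values("volume_index")
        censor_masks.append(t["censored"].to_numpy().astype(bool))
        state_labels.append(t[["macro", "sub"]].to_numpy())
    return {
        "subject_ids": list(subjects["subject_id"]),
        "group_labels": list(subjects["group"]),
        "series": series,
        "mask": mask,
        "network_maps": maps,
        "ownership": ownership,
        "censor_masks": censor_masks,
        "state_labels": state_labels,
    }
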