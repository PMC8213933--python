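"""Plain matplotlib reporting helpers (PNG heatmap, z-map slice montage)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_cap_rsn_heatmap", "plot_zmap_slices"]

# display-only z window used when rendering CAP maps (not an analysis
# threshold): values with |z| below the lower bound are hidden, the colour
# scale saturates at the upper bound
ZMAP_DISPLAY_WINDOW = (3.5, 20.0)


def plot_cap_rsn_heatmap(mean_z, path, row_order=None, col_order=None,
                         decile_masks=None, cmap="RdBu_r"):
    """Networks x CAPs mean-z heatmap with optional decile highlighting.

    ``decile_masks`` may map a direction name to a boolean DataFrame; flagged
    cells are annotated with the first letter of the direction key.
    """
    M = mean_z
    if row_order is not None:
        M = M.iloc[row_order]
    if col_order is not None:
        M = M.iloc[:, col_order]
    vmax = np.nanmax(np.abs(M.to_numpy())) or 1.0
    fig, ax = plt.subplots(figsize=(max(6, 0.28 * M.shape[1]),
                                    max(4, 0.3 * M.shape[0])))
    im = ax.imshow(M.to_numpy(), cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(M.shape[1]))
    ax.set_xticklabels(M.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(M.shape[0]))
    ax.set_yticklabels(M.index, fontsize=7)
    if decile_masks:
        for name, dm in decile_masks.items():
            dmo = dm
            if row_order is not None:
                dmo = dmo.iloc[row_order]
            if col_order is not None:
                dmo = dmo.iloc[:, col_order]
            ys, xs = np.nonzero(dmo.to_numpy())
            for y, x in zip(ys, xs):
                ax.text(x, y, name[0].upper(), ha="center", va="center",
                        fontsize=6, fontweight="bold")
    fig.colorbar(im, ax=ax, label="mean z")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_zmap_slices(zvol: np.ndarray, path, n_slices: int = 6,
                     window=ZMAP_DISPLAY_WINDOW):
    """Axial slice montage of a 3D z map with the display window applied."""
    lo, hi = window
    shown = np.where(np.abs(np.nan_to_num(zvol)) >= lo, zvol, np.nan)
    zdim = zvol.shape[2]
    picks = np.linspace(0, zdim - 1, n_slices).astype(int)
    fig, axes = plt.subplots(1, n_slices, figsize=(2 * n_slices, 2.2))
    for ax, zi in zip(np.atleast_1d(axes), picks):
        ax.imshow(np.nan_to_num(zvol[:, :, zi]).T, cmap="gray", alpha=0.4)
        ax.imshow(shown[:, :, zi].T, cmap="RdBu_r", vmin=-hi, vmax=hi)
        ax.set_title(f"z={zi}", fontsize=7)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
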