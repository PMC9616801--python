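"""Figure helpers: similarity matrices, lag profiles, effect distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_similarity_matrix(values: np.ndarray, path: str | Path, title: str = "",
                           vmin: float = -1.0, vmax: float = 1.0) -> None:
    fig, ax = plt.subplots(figsize=(4, 3.4))
    im = ax.imshow(values, vmin=vmin, vmax=vmax, cmap="RdBu_r", origin="lower")
    ax.set_xlabel("silencing window")
    ax.set_ylabel("silencing window")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="cross-validated cos")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lag_profiles(profiles: dict, path: str | Path, lag_step_ms: float = 66.0,
                      ylabel: str = "cross-validated cos") -> None:
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    for label, prof in profiles.items():
        prof = np.asarray(prof, dtype=float)
        ax.plot(np.arange(prof.size) * lag_step_ms, prof, "o-", label=label)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_effect_distribution(percent_change: np.ndarray, path: str | Path,
                             title: str = "") -> None:
    vals = np.asarray(percent_change, dtype=float)
    vals = vals[np.isfinite(vals)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(vals, bins=40, color="0.4")
    ax.axvline(np.median(vals), color="crimson", label=f"median {np.median(vals):.1f}%")
    ax.set_xlabel("silencing effect (%)")
    ax.set_ylabel("neurons x windows")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
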