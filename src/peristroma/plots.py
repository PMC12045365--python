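"""ECDF-overlay and ladder figures for bias reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import avatar as avatar_null
from . import metrics


def ecdf_overlay(profile, path=None, title: str = ""):
    """Observed positive-cell ECDF vs the expected avatar-null ECDF,
    with the KS D annotated."""
    obs = metrics.ecdf(profile.positive_distances)
    null = avatar_null.expected_null_ecdf(profile)
    d, _ = metrics.ks_statistic(profile.positive_distances, profile.distances)

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    grid = np.linspace(0, float(null.support.max()), 512)
    ax.step(grid, obs.evaluate(grid), where="post", label="observed positives", lw=1.5)
    ax.step(grid, null.evaluate(grid), where="post", label="expected null (all cells)",
            lw=1.5, ls="--")
    ax.set_xlabel("distance to nearest stroma (µm)")
    ax.set_ylabel("cumulative fraction")
    ax.annotate(f"KS D = {d:.3f}", xy=(0.62, 0.15), xycoords="axes fraction")
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def ladder_plot(summaries, statistic: str = "median", path=None):
    """Paired predicted->observed segments, one per tumor, grouped by
    (treatment, host model)."""
    key = lambda s: (s.treatment, s.host_model)
    groups = sorted({key(s) for s in summaries})
    fig, ax = plt.subplots(figsize=(1.2 + 1.6 * len(groups), 3.5))
    for gi, g in enumerate(groups):
        members = [s for s in summaries if key(s) == g]
        x0, x1 = gi - 0.18, gi + 0.18
        for s in members:
            pred = getattr(s, f"null_{statistic}")
            obs = getattr(s, f"observed_{statistic}")
            ax.plot([x0, x1], [pred, obs], "-o", color="0.3", ms=3, lw=0.8)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(["\n".join(filter(None, g)) or "all" for g in groups], fontsize=8)
    ax.set_ylabel(f"{statistic} distance to stroma (µm)\npredicted → observed")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
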