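"""Optional diagnostic plots (Bland-Altman and mountain)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .agreement_stats import PairedGfr, Scale, bland_altman, mountain_curve

__all__ = ["plot_bland_altman", "plot_mountain"]


def plot_bland_altman(
    pairs: Sequence[PairedGfr],
    path: str | Path,
    scale: Scale = "percent_of_reference",
    title: str = "",
) -> None:
    ba = bland_altman(pairs, scale)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=14, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    unit = "%" if scale == "percent_of_reference" else "mL/min/1.73 m$^2$"
    ax.set_xlabel("mean of methods (mL/min/1.73 m$^2$)")
    ax.set_ylabel(f"test $-$ reference ({unit})")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mountain(
    pairs: Sequence[PairedGfr],
    path: str | Path,
    scale: Scale = "percent_of_reference",
    title: str = "",
) -> None:
    mc = mountain_curve(pairs, scale)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(mc.diffs, mc.folded_percentile, marker=".", linewidth=1)
    ax.axvline(0.0, color="k", linewidth=0.8)
    unit = "%" if scale == "percent_of_reference" else "mL/min/1.73 m$^2$"
    ax.set_xlabel(f"reference $-$ test ({unit})")
    ax.set_ylabel("folded percentile")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
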