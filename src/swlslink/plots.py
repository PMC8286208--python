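"""Plotting utilities: Bland-Altman plots and normality screening.

Normality screening (histogram + normal QQ) is provided for visual
inspection only; nothing in the pipeline gates on a formal normality test.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering; callers only write files

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .agreement import LimitsOfAgreement, PairedScores

__all__ = ["bland_altman_plot", "score_distribution_plot"]


def bland_altman_plot(
    p: PairedScores,
    loa: LimitsOfAgreement,
    title: str = "Bland-Altman plot",
    out_path: str | None = None,
    jitter: float = 0.0,
    seed: int = 0,
):
    """Difference vs pair-mean scatter with mean line and 95% limits.

    The mean difference is drawn as a dotted line and the limits of
    agreement as dashed lines.  Scores are discrete (quarter-point grid), so
    an optional uniform jitter can be added for overplotting; it is off by
    default and affects display only.
    """
    mean_pair = (p.direct + p.prorated) / 2
    diff = p.differences
    if jitter > 0:
        rng = np.random.default_rng(seed)
        mean_pair = mean_pair + rng.uniform(-jitter, jitter, size=mean_pair.size)
        diff = diff + rng.uniform(-jitter, jitter, size=diff.size)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(mean_pair, diff, s=8, alpha=0.35, edgecolors="none", color="#1f5fa8")
    ax.axhline(loa.mean_diff, linestyle=":", color="black", linewidth=1.2,
               label=f"mean difference ({loa.mean_diff:.2f})")
    for bound, name in ((loa.lower, "lower"), (loa.upper, "upper")):
        ax.axhline(bound, linestyle="--", color="0.3", linewidth=1.2,
                   label=f"{name} 95% limit ({bound:.2f})")
    ax.set_xlabel("Mean of direct and prorated score")
    ax.set_ylabel("Direct − prorated score")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return None
    return fig


def score_distribution_plot(scores, title: str = "Score distribution",
                            out_path: str | None = None):
    """Histogram plus normal QQ plot for visual normality screening."""
    x = np.asarray(list(scores), dtype=float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.hist(x, bins="auto", color="#1f5fa8", edgecolor="white")
    ax1.set_xlabel("Score")
    ax1.set_ylabel("Count")
    ax1.set_title(title)
    stats.probplot(x, dist="norm", plot=ax2)
    ax2.set_title("Normal QQ")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return None
    return fig
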