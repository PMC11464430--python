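"""Analytical greenness scoring over the twelve green-analytical-chemistry criteria.

Each criterion is scored in [0, 1] and carries a positive weight; the overall
score is the weighted arithmetic mean

    overall = sum(w_i * s_i) / sum(w_i)

rendered as a colour wheel whose hue bands run from red (not green at all)
to dark green.  An overall score of 0.75 or above marks a method with
notable environmental sustainability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

N_CRITERIA = 12

#: Default render bands: [0, 0.25) red, [0.25, 0.5) orange, [0.5, 0.75)
#: yellow-green, [0.75, 1] dark green.
DEFAULT_BANDS = ((0.25, "red"), (0.5, "orange"), (0.75, "yellow-green"), (1.0 + 1e-12, "dark green"))


@dataclass(frozen=True)
class GreennessAssessment:
    criterion_scores: tuple[float, ...]
    weights: tuple[float, ...]
    overall: float
    bands: tuple[str, ...]


def overall_score(scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted arithmetic mean of the twelve criterion scores."""
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.size != N_CRITERIA or w.size != N_CRITERIA:
        raise ValueError(f"expected {N_CRITERIA} scores and weights, got {s.size} and {w.size}")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("criterion scores must lie in [0, 1]")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    return float(np.dot(s, w) / w.sum())


def color_band(score: float, bands=DEFAULT_BANDS) -> str:
    """Map a score in [0, 1] onto its render colour band."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [0, 1], got {score}")
    for upper, name in bands:
        if score < upper:
            return name
    return bands[-1][1]


def assess(scores: Sequence[float], weights: Sequence[float]) -> GreennessAssessment:
    """Score and band all criteria plus the overall result."""
    overall = overall_score(scores, weights)
    return GreennessAssessment(
        criterion_scores=tuple(float(x) for x in scores),
        weights=tuple(float(x) for x in weights),
        overall=overall,
        bands=tuple(color_band(s) for s in scores),
    )


def plot_wheel(assessment: GreennessAssessment, path: str) -> None:
    """Render the colour-wheel summary (overall score in the centre) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"red": "#d7191c", "orange": "#fdae61", "yellow-green": "#a6d96a", "dark green": "#1a9641"}
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    n = len(assessment.criterion_scores)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    width = 2 * np.pi / n
    ax.bar(theta, np.ones(n), width=width, bottom=0.35,
           color=[colors[b] for b in assessment.bands], edgecolor="white")
    for ang, i in zip(theta, range(n)):
        ax.text(ang, 0.95, str(i + 1), ha="center", va="center", fontsize=8)
    ax.text(0, 0, f"{assessment.overall:.2f}", ha="center", va="center", fontsize=16,
            color=colors[color_band(assessment.overall)])
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
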