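"""Validation figures: ROC, calibration, score distribution, cohort overlays.

Every function writes both SVG and PNG next to each other (``stem.svg`` /
``stem.png``) and returns the figure for further tweaking.  SVG metadata is
stripped of dates so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

plt.rcParams["svg.hashsalt"] = "gpospom"  # deterministic SVG element ids

from .validation_metrics import CalibrationFit, PerScoreMortality, RocCurve

_SVG_META = {"Date": None, "Creator": None}


def _save(fig, stem: str | Path) -> list[Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = [stem.with_suffix(".svg"), stem.with_suffix(".png")]
    fig.savefig(paths[0], metadata=_SVG_META)
    fig.savefig(paths[1], dpi=150)
    plt.close(fig)
    return paths


def plot_roc(curve: RocCurve, stem: str | Path) -> list[Path]:
    """ROC curve with the chance diagonal and the AUC in the legend."""
    fig, ax = plt.subplots(figsize=(5, 5))
    xs, ys = zip(*curve.points)
    ax.plot(xs, ys, color="#d1495b", lw=1.5, label=f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8, ls="--")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("Receiver operating characteristic")
    ax.legend(loc="lower right")
    ax.set_aspect("equal")
    return _save(fig, stem)


def plot_calibration(fit: CalibrationFit, stem: str | Path) -> list[Path]:
    """Observed vs predicted mortality per score value, identity diagonal and
    the fitted least-squares line."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    x = np.array([p for p, _, _ in fit.points])
    y = np.array([o for _, o, _ in fit.points])
    lim = max(1e-6, float(max(x.max(), y.max()))) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8, label="perfect calibration")
    grid = np.linspace(0, lim, 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, color="#1f77b4", lw=1.5,
            label=f"fit: slope {fit.slope:.2f}, intercept {fit.intercept:.4f}")
    ax.scatter(x, y, s=14, color="black", zorder=3, label="per-score observed")
    ax.set_xlabel("Predicted in-hospital mortality")
    ax.set_ylabel("Observed in-hospital mortality")
    ax.set_title("Calibration")
    ax.legend(loc="upper left", fontsize=8)
    return _save(fig, stem)


def plot_score_distribution(
    per_score: PerScoreMortality,
    stem: str | Path,
    max_score_axis: int | None = None,
) -> list[Path]:
    """Score histogram (share of cases) with per-score observed mortality
    overlaid on a secondary axis."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    scores = sorted(per_score.rows)
    total = per_score.total_cases or 1
    counts = [per_score.rows[s][0] / total * 100 for s in scores]
    mort = [per_score.rows[s][2] for s in scores]
    ax.bar(scores, counts, color="#e8871e", alpha=0.8, label="share of cases")
    ax.set_xlabel("Score value")
    ax.set_ylabel("Share of cases (%)")
    ax2 = ax.twinx()
    ax2.plot(scores, mort, color="#d1495b", lw=1.5, label="observed mortality")
    ax2.set_ylabel("Observed in-hospital mortality (%)")
    if max_score_axis is not None:
        ax.set_xlim(-0.5, max_score_axis + 0.5)
    h1, l1 = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(h1 + h2, l1 + l2, loc="upper right", fontsize=8)
    ax.set_title("Score distribution and observed mortality")
    return _save(fig, stem)


def plot_cohort_comparison(
    per_score: PerScoreMortality,
    reference: Mapping[int, float],
    stem: str | Path,
    quantity: str = "share",
    reference_label: str = "reference cohort",
) -> list[Path]:
    """Overlay this cohort against a reference distribution.

    ``reference`` maps score -> percentage (share of cases or mortality,
    per ``quantity``), e.g. digitised from another validation cohort.
    """
    fig, ax = plt.subplots(figsize=(7, 4.5))
    scores = sorted(per_score.rows)
    total = per_score.total_cases or 1
    if quantity == "share":
        own = [per_score.rows[s][0] / total * 100 for s in scores]
        ylabel = "Share of cases (%)"
        ax.bar(scores, own, color="#e8871e", alpha=0.7, label="this cohort")
        ref_scores = sorted(reference)
        ax.bar(ref_scores, [reference[s] for s in ref_scores], color="grey",
               alpha=0.5, label=reference_label)
    else:
        own = [per_score.rows[s][2] for s in scores]
        ylabel = "Observed in-hospital mortality (%)"
        ax.plot(scores, own, color="#d1495b", lw=1.5, label="this cohort")
        ref_scores = sorted(reference)
        ax.plot(ref_scores, [reference[s] for s in ref_scores], color="grey",
                lw=1.5, label=reference_label)
    ax.set_xlabel("Score value")
    ax.set_ylabel(ylabel)
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("Cohort comparison")
    return _save(fig, stem)
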