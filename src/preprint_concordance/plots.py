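"""Paired forest plot of preprint vs article effect estimates.

Each discrepant trial x outcome renders two adjacent lines — the preprint
estimate and the article estimate — on a log-scaled horizontal axis with a
vertical reference line at RR = 1 and per-arm n/N annotations, the standard
display for side-by-side comparison of ratio-scale estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless backend; file output only
import matplotlib.pyplot as plt

from .concordance import MatchStatus, classify_trial
from .data_model import DocType, OutcomeReport, TrialPair

__all__ = ["ForestRow", "forest_plot", "discrepant_forest_rows"]


@dataclass(frozen=True)
class ForestRow:
    """One line of the paired forest display."""

    trial_label: str
    outcome_label: str
    document: DocType
    point: float
    ci_low: float
    ci_high: float
    annotation: str  # "n/N vs n/N" event/analyzed strings per arm

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket "
                f"point {self.point}"
            )


def _annotation(rep: OutcomeReport) -> str:
    return (f"{rep.events_intervention}/{rep.n_intervention} vs "
            f"{rep.events_control}/{rep.n_control}")


def discrepant_forest_rows(trials: Sequence[TrialPair],
                           alpha: float = 0.05) -> list[ForestRow]:
    """Preprint/article row pairs for every matched outcome whose counts
    changed between documents, ordered by trial label then outcome."""
    rows: list[ForestRow] = []
    for pair in sorted(trials, key=lambda t: t.trial_id):
        concordance = classify_trial(pair, alpha)
        for comp in concordance.comparisons:
            if comp.status is not MatchStatus.MATCHED:
                continue
            if not (comp.events_changed or comp.n_changed):
                continue
            if not (comp.preprint_estimate.estimable and comp.article_estimate.estimable):
                continue
            for doc_type, est, rep in (
                (DocType.PREPRINT, comp.preprint_estimate,
                 pair.preprint.outcomes[comp.outcome]),
                (DocType.ARTICLE, comp.article_estimate,
                 pair.article.outcomes[comp.outcome]),
            ):
                rows.append(ForestRow(
                    trial_label=pair.trial_id,
                    outcome_label=comp.outcome.label,
                    document=doc_type,
                    point=est.point,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    annotation=_annotation(rep),
                ))
    return rows


def forest_plot(rows: Sequence[ForestRow], output: Optional[str] = None):
    """Render the paired forest plot; save to ``output`` when given.

    Returns the matplotlib Figure so callers (and tests) can inspect the data
    layer. Layout is deterministic for fixed input.
    """
    if not rows:
        raise ValueError("forest_plot requires at least one pair of rows")
    if len(rows) % 2 != 0:
        raise ValueError("rows must come in preprint/article pairs")

    n = len(rows)
    fig, ax = plt.subplots(figsize=(8.0, 0.45 * n + 1.5))
    ypos = []
    y = 0.0
    for i, row in enumerate(rows):
        ypos.append(y)
        # extra gap after each preprint/article pair
        y -= 1.0 if (i % 2 == 0) else 1.6

    colors = {DocType.PREPRINT: "#1f77b4", DocType.ARTICLE: "#d62728"}
    for row, yy in zip(rows, ypos):
        ax.errorbar(
            [row.point], [yy],
            xerr=[[row.point - row.ci_low], [row.ci_high - row.point]],
            fmt="s", color=colors[row.document], capsize=3, markersize=5,
        )
        label = f"{row.trial_label} | {row.outcome_label} | {row.document.value}"
        ax.annotate(label, xy=(0, yy), xycoords=("axes fraction", "data"),
                    xytext=(-6, 0), textcoords="offset points",
                    ha="right", va="center", fontsize=8)
        ax.annotate(row.annotation, xy=(1, yy), xycoords=("axes fraction", "data"),
                    xytext=(6, 0), textcoords="offset points",
                    ha="left", va="center", fontsize=8)

    ax.axvline(1.0, color="0.4", linewidth=0.8, linestyle="--")
    ax.set_xscale("log")
    ax.set_yticks([])
    ax.set_xlabel("risk ratio (log scale)")
    ax.set_ylim(min(ypos) - 1.0, 1.0)
    fig.tight_layout()
    if output is not None:
        out = Path(output)
        try:
            fig.savefig(out)
        except OSError as exc:
            plt.close(fig)
            raise OSError(f"cannot write forest plot to {out}: {exc}") from exc
    return fig
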