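"""Cumulative variance-explained curves and tweets-per-topic model selection.

The explained fraction after t topics is ``e_t = 1 - residual_frob2_after[t]
/ original_frob2``, computed exactly from the norms stored during fitting (no
refitting noise). Models differing only in tweets-per-topic (m) are compared
by these curves; the winner is the setting that reaches a target explained
fraction in the fewest topics, with ties resolved toward higher coverage at
that point and then the smaller m.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .spca import SpcaConfig, TopicModel, fit_topic_model
from .term_matrix import TermDocMatrix

__all__ = [
    "VarianceCurve",
    "ModelComparison",
    "variance_curve",
    "topics_to_threshold",
    "compare_models",
    "comparison_to_csv",
    "plot_comparison",
]


@dataclass(frozen=True)
class VarianceCurve:
    """Points (t, e_t) with e_0 = 0, e_t non-decreasing and within [0, 1]."""

    m_docs: int
    points: tuple[tuple[int, float], ...]

    def __post_init__(self):
        if not self.points or self.points[0] != (0, 0.0):
            raise ValueError("curve must start at (0, 0.0)")
        prev = -1.0
        for t, e in self.points:
            if e < -1e-12 or e > 1.0 + 1e-12:
                raise ValueError(f"explained fraction {e} outside [0, 1]")
            if e < prev - 1e-12:
                raise ValueError("explained fraction must be non-decreasing")
            prev = e

    @property
    def explained(self) -> tuple[float, ...]:
        return tuple(e for _, e in self.points)

    @property
    def final_explained(self) -> float:
        return self.points[-1][1]


def variance_curve(model: TopicModel) -> VarianceCurve:
    """Exact curve from the model's stored residual trace."""
    if model.original_frob2 <= 0.0:
        raise ValueError("model has zero original Frobenius norm; no variance to explain")
    pts = [(0, 0.0)]
    for t, r in enumerate(model.residual_frob2_after, start=1):
        pts.append((t, 1.0 - r / model.original_frob2))
    return VarianceCurve(m_docs=model.config.m_docs, points=tuple(pts))


def topics_to_threshold(curve: VarianceCurve, threshold: float) -> int | None:
    """Smallest t >= 1 with e_t >= threshold, or None when never reached.

    At threshold 0 this is the first topic that removed any document mass.
    """
    for t, e in curve.points[1:]:
        if e >= threshold:
            return t
    return None


@dataclass(frozen=True)
class ModelComparison:
    """Curves per tweets-per-topic setting plus the scalar winner summary."""

    curves: Mapping[int, VarianceCurve]
    models: Mapping[int, TopicModel]
    threshold: float
    topics_at_threshold: Mapping[int, int | None]
    winner: int

    def divergence(self, eps: float = 1e-12) -> int | None:
        """First topic count at which any two curves differ by more than eps."""
        settings = sorted(self.curves)
        t_max = min(len(self.curves[m].points) for m in settings)
        for t in range(t_max):
            vals = [self.curves[m].points[t][1] for m in settings]
            if max(vals) - min(vals) > eps:
                return t
        return None


def compare_models(
    tdm: TermDocMatrix,
    settings: Sequence[int] = (10, 15, 20),
    threshold: float = 0.90,
    config: SpcaConfig | None = None,
) -> ModelComparison:
    """Fit one model per tweets-per-topic setting on identical input.

    Each fit starts from the same matrix (no shared residual state). The
    threshold is a convenience summary of the full curves, which are kept.
    """
    if not settings:
        raise ValueError("at least one tweets-per-topic setting required")
    base = config or SpcaConfig()
    curves: dict[int, VarianceCurve] = {}
    models: dict[int, TopicModel] = {}
    reach: dict[int, int | None] = {}
    for m in sorted(set(settings)):
        model = fit_topic_model(tdm, replace(base, m_docs=m))
        models[m] = model
        curves[m] = variance_curve(model)
        reach[m] = topics_to_threshold(curves[m], threshold)

    def _rank(m: int):
        t = reach[m]
        cover = curves[m].points[t][1] if t is not None else curves[m].final_explained
        # fewest topics to threshold; then larger coverage there; then smaller m
        return (t if t is not None else float("inf"), -cover, m)

    winner = min(curves, key=_rank)
    return ModelComparison(
        curves=curves, models=models, threshold=threshold, topics_at_threshold=reach, winner=winner
    )


def comparison_to_csv(comparison: ModelComparison, path: str | Path) -> None:
    """Tidy CSV: setting, t, explained_fraction."""
    rows = [
        (m, t, e)
        for m in sorted(comparison.curves)
        for t, e in comparison.curves[m].points
    ]
    pd.DataFrame(rows, columns=["setting", "t", "explained_fraction"]).to_csv(path, index=False)


def plot_comparison(comparison: ModelComparison, path: str | Path, title: str = "") -> None:
    """Overlay the variance-explained curves for the compared settings."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for m in sorted(comparison.curves):
        curve = comparison.curves[m]
        ts = [t for t, _ in curve.points]
        es = [e for _, e in curve.points]
        ax.plot(ts, es, label=f"{m} tweets/topic")
    ax.axhline(comparison.threshold, color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel("number of topics")
    ax.set_ylabel("cumulative fraction of variance explained")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": "sparsetopics"} if str(path).endswith(".png") else None)
    plt.close(fig)
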