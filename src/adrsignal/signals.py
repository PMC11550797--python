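"""Credible-interval summaries and light/strong predictor classification.

Each coefficient's posterior is summarized by its median and equal-tailed
50% and 90% credible intervals.  A predictor whose 50% interval lies
entirely above zero is classified *light positive*, upgraded to *strong
positive* when the 90% interval also excludes zero; negative predictors
mirror the rule.  An interval endpoint exactly at zero counts as covering
zero (the conservative reading).  Negative classifications are reported but
should not be read as evidence of a protective effect: in adverse-event
registries they typically reflect the case/non-case construction rather
than pharmacology.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples

__all__ = [
    "CoefficientSummary",
    "SignalClass",
    "SignalTable",
    "credible_interval",
    "classify",
    "summarize_posterior",
    "build_signal_table",
    "forest_plot",
]


def credible_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval at the given level.

    Quantiles at (1-level)/2 and 1-(1-level)/2 with linear interpolation
    between order statistics.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least two draws for a credible interval")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class CoefficientSummary:
    """Posterior median and nested 50%/90% equal-tailed intervals."""

    name: str
    median: float
    ci50: tuple[float, float]
    ci90: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.ci90[0] <= self.ci50[0] <= self.median
                <= self.ci50[1] <= self.ci90[1]):
            raise ValueError(f"intervals of {self.name!r} are not nested")

    @classmethod
    def from_draws(cls, name: str, draws: np.ndarray,
                   level_light: float = 0.5,
                   level_strong: float = 0.9) -> "CoefficientSummary":
        return cls(
            name=name,
            median=float(np.median(draws)),
            ci50=credible_interval(draws, level_light),
            ci90=credible_interval(draws, level_strong),
        )


class SignalClass(enum.Enum):
    STRONG_POSITIVE = "strong_positive"
    LIGHT_POSITIVE = "light_positive"
    NONE = "none"
    LIGHT_NEGATIVE = "light_negative"
    STRONG_NEGATIVE = "strong_negative"


def classify(summary: CoefficientSummary) -> SignalClass:
    """Classify one predictor from its 50%/90% credible intervals."""
    lo50, hi50 = summary.ci50
    lo90, hi90 = summary.ci90
    if lo50 > 0.0:
        return SignalClass.STRONG_POSITIVE if lo90 > 0.0 else SignalClass.LIGHT_POSITIVE
    if hi50 < 0.0:
        return SignalClass.STRONG_NEGATIVE if hi90 < 0.0 else SignalClass.LIGHT_NEGATIVE
    return SignalClass.NONE


def summarize_posterior(samples: PosteriorSamples,
                        level_light: float = 0.5,
                        level_strong: float = 0.9) -> list[CoefficientSummary]:
    """Coefficient summaries for every predictor of a fitted model."""
    flat = samples.beta.reshape(-1, samples.beta.shape[-1])
    return [
        CoefficientSummary.from_draws(name, flat[:, j], level_light, level_strong)
        for j, name in enumerate(samples.predictor_names)
    ]


_CLASS_ORDER = {
    SignalClass.STRONG_POSITIVE: 0,
    SignalClass.LIGHT_POSITIVE: 1,
    SignalClass.NONE: 2,
    SignalClass.LIGHT_NEGATIVE: 3,
    SignalClass.STRONG_NEGATIVE: 4,
}


@dataclass
class SignalTable:
    """Per-predictor intervals and classifications, drugs and covariates apart.

    Both frames carry the columns name, median, ci50_lo, ci50_hi, ci90_lo,
    ci90_hi, signal_class, bold_50 and bold_90 (the boldness flags marking
    intervals that exclude zero), sorted strong before light with
    descending median within class.
    """

    drugs: pd.DataFrame
    covariates: pd.DataFrame

    def positive(self) -> pd.DataFrame:
        """Drug rows classified at least light positive."""
        mask = self.drugs["signal_class"].isin(
            [SignalClass.STRONG_POSITIVE.value, SignalClass.LIGHT_POSITIVE.value])
        return self.drugs[mask].reset_index(drop=True)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        drugs = self.drugs.assign(block="drug")
        covs = self.covariates.assign(block="covariate")
        pd.concat([drugs, covs], ignore_index=True).to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        import json

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"drugs": self.drugs.to_dict(orient="records"),
                   "covariates": self.covariates.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2))
        return path


def _table_rows(summaries: Iterable[CoefficientSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        cls = classify(s)
        rows.append({
            "name": s.name,
            "median": s.median,
            "ci50_lo": s.ci50[0], "ci50_hi": s.ci50[1],
            "ci90_lo": s.ci90[0], "ci90_hi": s.ci90[1],
            "signal_class": cls.value,
            "bold_50": cls is not SignalClass.NONE,
            "bold_90": cls in (SignalClass.STRONG_POSITIVE, SignalClass.STRONG_NEGATIVE),
            "_order": _CLASS_ORDER[cls],
        })
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["name", "median", "ci50_lo", "ci50_hi",
                                     "ci90_lo", "ci90_hi", "signal_class",
                                     "bold_50", "bold_90"])
    frame = frame.sort_values(["_order", "median"], ascending=[True, False],
                              kind="mergesort")
    return frame.drop(columns="_order").reset_index(drop=True)


def build_signal_table(summaries: Sequence[CoefficientSummary],
                       covariate_names: Iterable[str] = ()) -> SignalTable:
    """Assemble the signal table, reporting covariates apart from drugs."""
    cov = set(covariate_names)
    return SignalTable(
        drugs=_table_rows([s for s in summaries if s.name not in cov]),
        covariates=_table_rows([s for s in summaries if s.name in cov]),
    )


def forest_plot(summaries: Sequence[CoefficientSummary], outcome_label: str,
                path: str | Path) -> Path:
    """Forest plot of coefficient posteriors.

    One row per predictor: a thick segment for the 50% interval, a thin one
    for the 90% interval, a dot at the median and a zero reference line.
    Row order follows the input order.  Output is deterministic vector
    graphics (SVG) given identical input.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one coefficient summary to plot")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "adrsignal",
                                "svg.fonttype": "none"}):
        n = len(summaries)
        fig, ax = plt.subplots(figsize=(7.0, max(2.0, 0.22 * n + 1.2)))
        ys = np.arange(n)[::-1]
        for s, yv in zip(summaries, ys):
            ax.plot(list(s.ci90), [yv, yv], lw=0.9, color="#4878a8",
                    solid_capstyle="butt", zorder=2)
            ax.plot(list(s.ci50), [yv, yv], lw=3.0, color="#1f4e79",
                    solid_capstyle="butt", zorder=3)
            ax.plot([s.median], [yv], marker="o", ms=2.5, color="black", zorder=4)
        ax.axvline(0.0, color="black", lw=0.8, zorder=1)
        ax.set_yticks(ys)
        ax.set_yticklabels([s.name for s in summaries], fontsize=6)
        ax.set_xlabel("posterior coefficient (log-odds)")
        ax.set_title(f"Posterior coefficients: {outcome_label}")
        fig.tight_layout()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)
    return path
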