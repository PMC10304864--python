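"""Experiment-level population dynamics summaries.

Covers the bookkeeping around serial-passage experiments: daily titer
trajectories with a plating detection limit, cross-streak resistance
fractions with their survey detection limit ``(1 - 1/n) * 100%``,
survival/extinction classification, efficiency of plating, and total test
accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TiterSeries:
    """Daily titers for one population; 0 / sub-limit values are treated as
    below the plating detection limit."""

    population: str
    days: tuple[int, ...]
    titers: tuple[float, ...]
    detection_limit: float = 100.0

    def __post_init__(self) -> None:
        if len(self.days) != len(self.titers):
            raise ValueError("days and titers must align")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if self.detection_limit <= 0:
            raise ValueError("detection limit must be positive")

    def below_detection(self) -> tuple[bool, ...]:
        return tuple(t < self.detection_limit for t in self.titers)


def titer_series_from_frame(
    df: pd.DataFrame, detection_limit: float = 100.0
) -> list[TiterSeries]:
    series = []
    for pop, group in df.groupby("population", sort=True):
        group = group.sort_values("day")
        series.append(
            TiterSeries(
                population=str(pop),
                days=tuple(int(d) for d in group["day"]),
                titers=tuple(float(t) for t in group["titer"]),
                detection_limit=detection_limit,
            )
        )
    return series


def detection_limit_pct(n_tested: int) -> float:
    """Largest resistant fraction distinguishable from fixation when testing
    n isolates: ``(1 - 1/n) * 100``."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    return (1.0 - 1.0 / n_tested) * 100.0


@dataclass(frozen=True)
class ResistancePoint:
    n_tested: int
    n_sensitive: int
    resistant_fraction: float
    at_detection_limit: bool  # no sensitive isolate found: fraction >= limit
    detection_limit_pct: float


def resistance_fraction(n_tested: int, n_sensitive: int) -> ResistancePoint:
    """Resistant fraction from a cross-streak survey.

    With zero sensitive isolates, complete resistance cannot be
    distinguished from any fraction at or above the survey's detection
    limit, so the point is flagged.
    """
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if not 0 <= n_sensitive <= n_tested:
        raise ValueError(f"n_sensitive {n_sensitive} outside [0, {n_tested}]")
    return ResistancePoint(
        n_tested=n_tested,
        n_sensitive=n_sensitive,
        resistant_fraction=(n_tested - n_sensitive) / n_tested,
        at_detection_limit=n_sensitive == 0,
        detection_limit_pct=detection_limit_pct(n_tested),
    )


@dataclass(frozen=True)
class FateResult:
    population: str
    fate: str  # "survival_bound" | "extinction_bound"
    extinction_day: Optional[int] = None


def classify_fate(series: TiterSeries) -> FateResult:
    """Extinction-bound iff the titer falls below the detection limit and
    never recovers through the final day; the extinction day is the first
    day of that terminal below-detection run."""
    if len(series.days) < 2:
        raise ValueError("need >= 2 days to classify a fate")
    below = series.below_detection()
    if not below[-1]:
        return FateResult(population=series.population, fate="survival_bound")
    # walk back through the terminal below-detection run
    i = len(below) - 1
    while i > 0 and below[i - 1]:
        i -= 1
    return FateResult(
        population=series.population,
        fate="extinction_bound",
        extinction_day=series.days[i],
    )


@dataclass(frozen=True)
class EfficiencyOfPlating:
    value: float
    is_upper_bound: bool = False


def efficiency_of_plating(
    test_titer, reference_titer: float, test_below_detection: bool = False
) -> EfficiencyOfPlating:
    """EOP = test titer / reference titer.

    A below-detection test titer (no plaques; pass the one-plaque bound as
    ``test_titer``) yields an upper bound. ``test_titer`` may be an
    :class:`~phage_evo.adsorption.Titer`, in which case its own
    below-detection flag is honoured.
    """
    below = test_below_detection or bool(getattr(test_titer, "below_detection", False))
    test = float(test_titer)
    if reference_titer <= 0:
        raise ValueError("reference titer must be positive")
    return EfficiencyOfPlating(value=test / reference_titer, is_upper_bound=below)


def experiment_accounting(design: Mapping[str, Sequence[int]]) -> int:
    """Total number of cross-streak tests: sum over populations and days."""
    return int(sum(sum(counts) for counts in design.values()))


def summarize_dynamics(
    titers: pd.DataFrame,
    resistance: pd.DataFrame,
    detection_limit: float = 100.0,
) -> dict:
    """JSON-ready summary: per-population fate and resistance trajectory."""
    fates = {
        s.population: classify_fate(s)
        for s in titer_series_from_frame(titers, detection_limit)
    }
    resistance_rows = []
    for _, row in resistance.iterrows():
        point = resistance_fraction(int(row["n_tested"]), int(row["n_sensitive"]))
        resistance_rows.append(
            {
                "population": row["population"],
                "day": int(row["day"]),
                "resistant_fraction": point.resistant_fraction,
                "at_detection_limit": point.at_detection_limit,
                "detection_limit_pct": point.detection_limit_pct,
            }
        )
    design = {
        str(pop): list(map(int, group.sort_values("day")["n_tested"]))
        for pop, group in resistance.groupby("population")
    }
    return {
        "fates": {
            pop: {"fate": f.fate, "extinction_day": f.extinction_day}
            for pop, f in fates.items()
        },
        "n_extinct": sum(f.fate == "extinction_bound" for f in fates.values()),
        "resistance": resistance_rows,
        "total_tests": experiment_accounting(design),
    }


def plot_dynamics(
    titers: pd.DataFrame,
    resistance: Optional[pd.DataFrame] = None,
    detection_limit: float = 100.0,
    path=None,
):
    """Trajectory plot (log titer per population, detection limit dashed)
    with an optional resistance panel; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 2 if resistance is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 4), squeeze=False)
    ax = axes[0, 0]
    for pop, group in titers.groupby("population"):
        group = group.sort_values("day")
        shown = np.maximum(group["titer"], detection_limit / 2)
        ax.plot(group["day"], shown, marker="o", ms=3, label=str(pop))
    ax.axhline(detection_limit, ls="--", c="gray", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("day")
    ax.set_ylabel("titer (PFU/mL)")
    ax.legend(fontsize=6)
    if resistance is not None:
        ax2 = axes[0, 1]
        for pop, group in resistance.groupby("population"):
            group = group.sort_values("day")
            frac = (group["n_tested"] - group["n_sensitive"]) / group["n_tested"]
            ax2.plot(group["day"], 100 * frac, marker="o", ms=3, label=str(pop))
        ax2.set_xlabel("day")
        ax2.set_ylabel("resistant (%)")
        ax2.set_ylim(0, 103)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
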