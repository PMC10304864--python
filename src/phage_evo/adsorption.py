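"""Adsorption-rate estimation from paired titers, with replicate statistics.

The rate constant follows the standard free-phage decay model: incubating
phage with cells at density ``N`` for time ``t`` leaves a fraction
``T1/T0 = exp(-delta * N * t)`` of free phage, so

    delta = -ln(T1 / T0) / (t * N)        [mL cell^-1 h^-1]

with time in hours. Replicates are summarised by a mean and a
t-distribution 95% CI; groups are compared with unpaired two-sample t tests
and Holm-Bonferroni multiple-testing correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class Titer:
    """A plate-count-derived titer; zero counts give a detection bound."""

    pfu_per_ml: float
    below_detection: bool = False

    def __float__(self) -> float:
        return self.pfu_per_ml


def titer_from_counts(
    plaque_count: int, dilution_factor: float, plated_volume_ml: float
) -> Titer:
    """PFU/mL from a plate count: ``count * dilution / volume``.

    Zero plaques are reported as below detection with the one-plaque
    equivalent titer as the upper bound.
    """
    if plaque_count < 0 or dilution_factor < 1 or plated_volume_ml <= 0:
        raise ValueError(
            "need count >= 0, dilution_factor >= 1 and plated volume > 0"
        )
    if plaque_count == 0:
        return Titer(
            pfu_per_ml=1 * dilution_factor / plated_volume_ml, below_detection=True
        )
    return Titer(pfu_per_ml=plaque_count * dilution_factor / plated_volume_ml)


def adsorption_rate(
    t0_titer: float, t1_titer: float, time_h: float, cell_density: float
) -> float:
    """Rate constant ``-ln(T1/T0) / (time_h * cell_density)``.

    ``T1 > T0`` (net phage growth) yields a negative rate with a warning;
    ``T1 = 0`` is rejected — report a lower bound from the detection limit
    instead.
    """
    t0 = float(t0_titer)
    t1 = float(t1_titer)
    if t0 <= 0 or time_h <= 0 or cell_density <= 0:
        raise ValueError("T0, time and cell density must be positive")
    if t1 == 0:
        raise ValueError(
            "T1 is zero: the rate is unbounded; report a lower bound using the "
            "assay's detection-limit titer instead"
        )
    if t1 > t0:
        warnings.warn(
            "T1 exceeds T0 (phage growth not fully blocked?); returning a "
            "negative rate",
            stacklevel=2,
        )
    return -math.log(t1 / t0) / (time_h * cell_density)


@dataclass(frozen=True)
class RateEstimate:
    n: int
    mean: float
    ci_low: float
    ci_high: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def summarize_replicates(rates: Sequence[float], confidence: float = 0.95) -> RateEstimate:
    """Mean and t-distribution CI over replicate rate estimates."""
    values = np.asarray(rates, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need >= 2 replicates for a CI")
    mean = float(values.mean())
    sem = float(values.std(ddof=1)) / math.sqrt(n)
    half = stats.t.ppf(0.5 + confidence / 2, df=n - 1) * sem
    return RateEstimate(n=n, mean=mean, ci_low=mean - half, ci_high=mean + half)


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float], tails: str = "two"
) -> tuple[float, float]:
    """Unpaired two-sample t test; one-tailed tests H1: mean(a) > mean(b).

    Two identical zero-variance groups return p = 1 by convention.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * math.inf, 0.0
    t_stat, p_two = stats.ttest_ind(a, b, equal_var=True)
    t_stat, p_two = float(t_stat), float(p_two)
    if tails == "two":
        return t_stat, p_two
    p_one = p_two / 2 if t_stat > 0 else 1 - p_two / 2
    return t_stat, p_one


@dataclass(frozen=True)
class HolmResult:
    p_values: list[float]
    adjusted: list[float]
    rejected: list[bool]
    alpha: float


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Holm's step-down correction: sort ascending, compare p_(i) with
    alpha/(m - i + 1), stop at the first failure; adjusted p values are
    monotone non-decreasing and capped at 1."""
    p = list(map(float, p_values))
    if not p:
        return HolmResult(p_values=[], adjusted=[], rejected=[], alpha=alpha)
    if min(p) < 0 or max(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    rejected, adjusted, *_ = multipletests(p, alpha=alpha, method="holm")
    return HolmResult(
        p_values=p,
        adjusted=[float(x) for x in adjusted],
        rejected=[bool(x) for x in rejected],
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# assay tables


def rates_from_assay_table(
    assays: pd.DataFrame, control: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-replicate rates from a plate-count assay table.

    Expected columns: replicate_id, host, phage, t0_count, t1_count,
    dilution_t0, dilution_t1, volume_mL, time_h, cell_density. When a
    no-cell ``control`` series is supplied (same replicate layout), its T1
    titer replaces T0 as the no-adsorption baseline. Replicates with zero
    T1 counts are dropped with a warning.
    """
    rows = []
    control_t1 = None
    if control is not None:
        control_t1 = {
            row["replicate_id"]: titer_from_counts(
                int(row["t1_count"]), float(row["dilution_t1"]), float(row["volume_mL"])
            )
            for _, row in control.iterrows()
        }
    for _, row in assays.iterrows():
        t0 = titer_from_counts(
            int(row["t0_count"]), float(row["dilution_t0"]), float(row["volume_mL"])
        )
        t1 = titer_from_counts(
            int(row["t1_count"]), float(row["dilution_t1"]), float(row["volume_mL"])
        )
        if control_t1 is not None:
            t0 = control_t1.get(row["replicate_id"], t0)
        if t1.below_detection:
            warnings.warn(
                f"replicate {row['replicate_id']}: zero T1 plaques, dropped "
                "(rate only bounded from below)",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "replicate_id": row["replicate_id"],
                "host": row.get("host", ""),
                "phage": row.get("phage", ""),
                "rate": adsorption_rate(
                    float(t0), float(t1), float(row["time_h"]), float(row["cell_density"])
                ),
            }
        )
    return pd.DataFrame(rows, columns=["replicate_id", "host", "phage", "rate"])
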