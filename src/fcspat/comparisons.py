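"""Non-spatial study statistics: size summaries, one-sided t-tests, ratios,
and infiltration-time descriptives.

The size question is directional by design — are the large gap features
significantly *larger* (or the small ones significantly *smaller*) than the
dead shrubs measured in the same plots? — hence one-sided two-sample
t-tests, Welch (unequal variance) by default. Infiltration times are
summarized descriptively (mean, median per region and position) without a
hypothesis test, mirroring how the measurements were reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DivisionByZeroError,
    EmptyGroupError,
    EmptyInputError,
    NonPositiveError,
    TooFewPointsError,
)

__all__ = [
    "SizeComparison",
    "InfiltrationSummary",
    "size_summary",
    "one_sided_t_test",
    "size_ratio",
    "infiltration_summary",
]


def size_summary(diameters) -> tuple[float, float, float, int]:
    """(min, max, mean, n) of a positive diameter sample (m)."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise EmptyInputError("no diameters supplied")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise NonPositiveError("diameters must be finite and strictly positive")
    return float(d.min()), float(d.max()), float(d.mean()), int(d.size)


@dataclass(frozen=True)
class SizeComparison:
    """One-sided two-sample t-test between two diameter groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    summary_a: tuple[float, float, float, int]  # (min, max, mean, n)
    summary_b: tuple[float, float, float, int]
    t: float
    df: float
    p_value: float
    direction: str  # "a_greater" | "a_less"
    variance: str  # "welch" | "pooled"


def one_sided_t_test(
    a,
    b,
    direction: str = "a_greater",
    variance: str = "welch",
    label_a: str = "a",
    label_b: str = "b",
) -> SizeComparison:
    """One-sided two-sample t-test on the difference of means.

    ``direction="a_greater"`` tests H1: mean(a) > mean(b);
    ``direction="a_less"`` tests H1: mean(a) < mean(b). Welch's
    unequal-variance form (with Welch-Satterthwaite df) is the default;
    ``variance="pooled"`` gives the classical equal-variance test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise TooFewPointsError("each group needs at least 2 observations")
    if direction not in ("a_greater", "a_less"):
        raise ValueError("direction must be 'a_greater' or 'a_less'")
    if variance not in ("welch", "pooled"):
        raise ValueError("variance must be 'welch' or 'pooled'")
    alternative = "greater" if direction == "a_greater" else "less"
    res = stats.ttest_ind(
        a, b, equal_var=(variance == "pooled"), alternative=alternative
    )
    return SizeComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        summary_a=(float(a.min()), float(a.max()), float(a.mean()), int(a.size)),
        summary_b=(float(b.min()), float(b.max()), float(b.mean()), int(b.size)),
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        direction=direction,
        variance=variance,
    )


def size_ratio(mean_a: float, mean_b: float) -> float:
    """Ratio of two group means (dimensionless)."""
    if mean_b <= 0:
        raise DivisionByZeroError("denominator mean must be positive")
    return float(mean_a) / float(mean_b)


@dataclass(frozen=True)
class InfiltrationSummary:
    """Descriptive summary of infiltration times for one region x position."""

    region: str
    position: str  # "inside" | "outside"
    times: np.ndarray
    mean: float
    median: float
    n: int


def infiltration_summary(samples: dict) -> list[InfiltrationSummary]:
    """Mean and median infiltration time per region x position.

    ``samples`` maps region name to a dict with keys "inside"/"outside"
    holding positive times in seconds (a single region may be passed as
    ``{"": {"inside": ..., "outside": ...}}`` or any region label).
    """
    out: list[InfiltrationSummary] = []
    for region, sides in samples.items():
        for position, times in sides.items():
            t = np.asarray(times, dtype=float)
            if t.size == 0:
                raise EmptyGroupError(f"no times for {region}/{position}")
            if np.any(t <= 0) or not np.all(np.isfinite(t)):
                raise NonPositiveError(
                    f"times for {region}/{position} must be finite and positive"
                )
            out.append(
                InfiltrationSummary(
                    region=region,
                    position=position,
                    times=t,
                    mean=float(t.mean()),
                    median=float(np.median(t)),
                    n=int(t.size),
                )
            )
    return out
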