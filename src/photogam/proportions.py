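"""Proportion-of-significance summaries and cross-regimen proportion tests.

The per-second significance trajectory is collapsed into one number per
photo-period set: the fraction of analyzed seconds where one group's EMM
significantly exceeds the other's *in a fixed, pre-declared direction*
(seconds significant in the opposite direction do not count).  Proportions
from different assay regimens are then compared with the two-proportions
z test with Yates' continuity correction, reported as the equivalent
1-df chi-squared statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .contrasts import ContrastTrajectory
from .regimen import Regimen, RegimenError

#: Default dark-phase period set: the 3rd, 4th and 5th dark periods of the
#: standard four-cycle repeat regimen.
DEFAULT_DARK_PERIODS = ("dark3", "dark4", "dark5")


class ProportionError(ValueError):
    """Invalid proportion computation request."""


@dataclass(frozen=True)
class PeriodProportion:
    """Directional proportion of significant seconds over a period set."""

    pair: tuple[str, str]
    direction: str  # level expected to be larger
    period_labels: tuple[str, ...]
    n_seconds: int
    n_significant: int
    alpha: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_significant <= self.n_seconds:
            raise ProportionError("n_significant must be within [0, n_seconds]")

    @property
    def proportion(self) -> float:
        return self.n_significant / self.n_seconds if self.n_seconds else 0.0

    @property
    def proportion_pct(self) -> float:
        """Proportion in percent, rounded to 2 decimals for reporting."""
        return round(100.0 * self.proportion, 2)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "pair": list(self.pair),
            "direction": self.direction,
            "periods": list(self.period_labels),
            "n": self.n_seconds,
            "x": self.n_significant,
            "proportion_pct": self.proportion_pct,
            "alpha": self.alpha,
        }


@dataclass(frozen=True)
class PropComparison:
    """Yates-corrected two-proportions z test, as a 1-df chi-squared."""

    a: PeriodProportion
    b: PeriodProportion
    chi2: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "a": self.a.to_dict(),
            "b": self.b.to_dict(),
            "chi2": self.chi2,
            "p": self.p_value,
        }


def proportion_significant(
    trajectory: ContrastTrajectory,
    regimen: Regimen,
    period_labels: tuple[str, ...] | list[str] = DEFAULT_DARK_PERIODS,
    pair: tuple[str, str] = ("WT", "HM"),
    direction: str | None = None,
    alpha: float = 0.05,
    label: str = "",
) -> PeriodProportion:
    """Directional proportion of significant seconds in the named periods.

    A second counts when the pair's Tukey-adjusted p is below ``alpha`` AND
    the difference favors ``direction`` (default: the first level of the
    pair).  ``n_seconds`` counts analyzed seconds (after any sampling
    stride), not wall-clock seconds.
    """
    a, b = pair
    direction = a if direction is None else direction
    if direction not in pair:
        raise ProportionError(f"direction {direction!r} must be one of {pair}")
    table = trajectory.pair_table(a, b)

    mask = np.zeros(len(table), dtype=bool)
    t = table["time_s"].to_numpy()
    for lab in period_labels:
        p = regimen.period(lab)  # raises RegimenError for unknown labels
        mask |= (t >= p.start_s) & (t < p.end_s)
    if not mask.any():
        raise ProportionError(
            f"trajectory covers no seconds of periods {tuple(period_labels)}"
        )
    sub = table.loc[mask]
    sig = (sub["p_adj"].to_numpy() < alpha) & (
        sub["direction"].to_numpy() == direction
    )
    return PeriodProportion(
        pair=(a, b),
        direction=direction,
        period_labels=tuple(period_labels),
        n_seconds=int(mask.sum()),
        n_significant=int(sig.sum()),
        alpha=alpha,
        label=label,
    )


def compare_proportions(a: PeriodProportion, b: PeriodProportion) -> PropComparison:
    """Two-proportions z test with Yates' continuity correction.

    chi2 = (max(|p1 - p2| - (1/n1 + 1/n2)/2, 0))^2
           / (pooled (1 - pooled) (1/n1 + 1/n2)),

    equivalent to the Yates-corrected chi-squared of the 2x2 contingency
    table of significant vs non-significant seconds; p from chi2 with 1 df.
    """
    n1, n2 = a.n_seconds, b.n_seconds
    if n1 <= 0 or n2 <= 0:
        raise ProportionError("both proportions need n_seconds > 0")
    x1, x2 = a.n_significant, b.n_significant
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn(
            "pooled proportion is degenerate (all or no seconds significant "
            "in both groups); test has zero power",
            RuntimeWarning,
        )
        return PropComparison(a=a, b=b, chi2=0.0, p_value=1.0)
    inv_n = 1.0 / n1 + 1.0 / n2
    num = max(abs(x1 / n1 - x2 / n2) - 0.5 * inv_n, 0.0)
    chi2 = num**2 / (pooled * (1.0 - pooled) * inv_n)
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return PropComparison(a=a, b=b, chi2=float(chi2), p_value=p)
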