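"""Coalescence vs infection-outcome association.

2x2 contingency analyses: Pearson's chi-square (1 df, no continuity
correction) and the odds ratio with a Woolf (log-scale normal) 95%
confidence interval.  Zero cells in the odds ratio receive a 0.5
continuity correction, flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable2x2", "chi_square", "odds_ratio", "coalescence_infection_table"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = (coalesced, infected), b = (coalesced, not),
    c = (non-coalesced, infected), d = (non-coalesced, not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (1 df, uncorrected)."""
    obs = t.matrix
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def odds_ratio(t: ContingencyTable2x2) -> dict:
    """Odds ratio ad/bc with Woolf 95% CI.

    Any zero cell triggers a 0.5 continuity correction of all four cells,
    reported via ``corrected=True``.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {
        "odds_ratio": or_,
        "ci_low": math.exp(math.log(or_) - 1.96 * se),
        "ci_high": math.exp(math.log(or_) + 1.96 * se),
        "corrected": corrected,
    }


def coalescence_infection_table(calls: pd.DataFrame, outcomes, window: str = "pre") -> ContingencyTable2x2:
    """Cross-tabulate eligible patients' coalescence status vs infection.

    ``window`` selects ``infection_pre`` (before neutrophil recovery) or
    ``infection_post90`` (the 90 days following recovery).
    """
    col = {"pre": "infection_pre", "post": "infection_post90"}[window]
    eligible = calls[calls["eligible"]]
    a = b = c = d = 0
    for _, row in eligible.iterrows():
        infected = bool(outcomes.records.loc[row["patient_id"], col])
        if row["coalesced"]:
            a, b = (a + 1, b) if infected else (a, b + 1)
        else:
            c, d = (c + 1, d) if infected else (c, d + 1)
    return ContingencyTable2x2(a, b, c, d)


def association_table(calls: pd.DataFrame, outcomes) -> pd.DataFrame:
    """Chi-square and odds-ratio summary for both infection windows."""
    rows = []
    for window, label in (("pre", "pre-recovery"), ("post", "post-recovery-90d")):
        t = coalescence_infection_table(calls, outcomes, window)
        stat, p = chi_square(t)
        orr = odds_ratio(t)
        rows.append(
            {
                "window": label,
                "chi_square": stat,
                "p": p,
                "odds_ratio": orr["odds_ratio"],
                "ci_low": orr["ci_low"],
                "ci_high": orr["ci_high"],
                "corrected": orr["corrected"],
            }
        )
    return pd.DataFrame(rows)
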