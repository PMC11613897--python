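"""Association statistics between family history, carrier status, and PRS.

Small kit for the correlation analyses: Fisher's exact test on a 2x2
cross-tab (with the sample odds ratio ad/bc and an exact conditional CI)
and Welch's unequal-variance t test.  By convention these analyses are run
on women *without* a breast-cancer diagnosis, restricted to the largest
genetic-similarity group so that standardized raw scores (not percentiles)
are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = exposed & outcome, b = exposed & no outcome,
    c = unexposed & outcome, d = unexposed & no outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact(t: TwoByTwo) -> tuple[float, float]:
    """Sample odds ratio (ad/bc, inf when bc = 0) and two-sided exact p.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (point-probability method).
    """
    tab = t.table
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero margin: odds ratio undefined")
    bc = t.b * t.c
    sample_or = math.inf if bc == 0 else (t.a * t.d) / bc
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return sample_or, float(p)


def odds_ratio_ci(t: TwoByTwo, confidence: float = 0.95) -> tuple[float, float]:
    """Exact conditional CI for the odds ratio (from the noncentral
    hypergeometric likelihood)."""
    res = stats.contingency.odds_ratio(t.table, kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence)
    return float(ci.low), float(ci.high)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's t statistic, Satterthwaite degrees of freedom, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    se2 = vx / x.size + vy / y.size
    tstat = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return float(tstat), float(df), float(p)


def carrier_fhx_association(
    carrier: np.ndarray, fhx: np.ndarray
) -> dict[str, float]:
    """Fisher test of carrier status against family history.

    Both inputs are boolean arrays over the analysis subset (typically
    women without a breast-cancer diagnosis).
    """
    carrier = np.asarray(carrier, dtype=bool)
    fhx = np.asarray(fhx, dtype=bool)
    t = TwoByTwo(
        a=int((carrier & fhx).sum()),
        b=int((carrier & ~fhx).sum()),
        c=int((~carrier & fhx).sum()),
        d=int((~carrier & ~fhx).sum()),
    )
    sample_or, p = fisher_exact(t)
    lo, hi = odds_ratio_ci(t)
    return {
        "odds_ratio": sample_or,
        "p_value": p,
        "or_ci_low": lo,
        "or_ci_high": hi,
        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
    }
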