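"""Evaluation of population genetic-screening strategies.

A screening strategy assigns each woman to a high-risk or average-risk
group from her carrier genes, group-specific PRS percentile, and recorded
family history.  Strategies are then compared on:

* positive predictive value — Kaplan-Meier probability of a breast-cancer
  diagnosis by age 70 among screen-positives,
* specificity — TN / (TN + FP), with negatives/positives weighted by their
  KM event probabilities by age 70,
* number needed to screen — 1 / (fraction screen-positive x fraction of
  positives diagnosed before age 50),
* false negatives — women diagnosed before age 50 the strategy missed.

Two reference strategies ship by default: #1 refers women with a family
history, a BRCA1/BRCA2/PALB2 pathogenic variant, or an ATM/CHEK2 variant
coupled with an above-median PRS; #2 drops family history and refers any
five-gene carrier or anyone in the top PRS decile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import GENES, HIGH_RISK_CUMINC_70
from .survival import KaplanMeier


@dataclass(frozen=True)
class StrategyDefinition:
    """One screening rule over family history, gene panels, and PRS."""

    name: str
    include_fhx: bool = False
    gene_panel_always: frozenset[str] = frozenset()
    gene_panel_conditional: frozenset[str] = frozenset()
    conditional_prs_top_fraction: float | None = None
    prs_top_fraction_standalone: float | None = None

    def __post_init__(self) -> None:
        for panel in (self.gene_panel_always, self.gene_panel_conditional):
            if set(panel) - set(GENES):
                raise ValueError(f"{self.name}: panel outside the 5-gene set")
        for f in (self.conditional_prs_top_fraction, self.prs_top_fraction_standalone):
            if f is not None and not 0.0 < f < 1.0:
                raise ValueError(f"{self.name}: PRS fraction must be in (0, 1)")
        if self.gene_panel_conditional and self.conditional_prs_top_fraction is None:
            raise ValueError(f"{self.name}: conditional panel needs a PRS fraction")


STRATEGY_1 = StrategyDefinition(
    name="strategy1_fhx_genes_prs",
    include_fhx=True,
    gene_panel_always=frozenset({"BRCA1", "BRCA2", "PALB2"}),
    gene_panel_conditional=frozenset({"ATM", "CHEK2"}),
    conditional_prs_top_fraction=0.50,
)

STRATEGY_2 = StrategyDefinition(
    name="strategy2_genes_or_top10prs",
    include_fhx=False,
    gene_panel_always=frozenset(GENES),
    prs_top_fraction_standalone=0.10,
)

DEFAULT_STRATEGIES = (STRATEGY_1, STRATEGY_2)


def assign_strategy(
    carrier_genes: Iterable[str],
    prs_percentile: float | None,
    fhx_positive: bool,
    strategy: StrategyDefinition,
) -> bool:
    """True when the participant lands in the strategy's high-risk group."""
    genes = set(carrier_genes)
    needs_prs = bool(genes & strategy.gene_panel_conditional) or (
        strategy.prs_top_fraction_standalone is not None
    )
    if needs_prs and prs_percentile is None:
        raise ValueError(f"{strategy.name}: PRS percentile required but missing")
    if strategy.include_fhx and fhx_positive:
        return True
    if genes & strategy.gene_panel_always:
        return True
    if genes & strategy.gene_panel_conditional:
        f = strategy.conditional_prs_top_fraction
        if prs_percentile > 100.0 * (1.0 - f):
            return True
    if strategy.prs_top_fraction_standalone is not None:
        if prs_percentile > 100.0 * (1.0 - strategy.prs_top_fraction_standalone):
            return True
    return False


# ---------------------------------------------------------------------------
# metric primitives (the printed arithmetic chains)
# ---------------------------------------------------------------------------

def ppv(km_event_prob_at70_positives: float) -> float:
    """PPV is *defined* as the KM event probability at 70 among positives."""
    if not 0.0 <= km_event_prob_at70_positives <= 1.0:
        raise ValueError("PPV input must be a probability")
    return float(km_event_prob_at70_positives)


def specificity(
    n_neg: float, p_event_neg: float, n_pos: float, p_noevent_pos: float
) -> float:
    """TN / (TN + FP) with KM-weighted true-negative and false-positive mass.

    TN = n_neg * (1 - p_event_neg): average-risk women free of a diagnosis
    by 70; FP = n_pos * p_noevent_pos: high-risk calls with no diagnosis.
    """
    if n_neg < 0 or n_pos < 0:
        raise ValueError("counts must be non-negative")
    for p in (p_event_neg, p_noevent_pos):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    tn = n_neg * (1.0 - p_event_neg)
    fp = n_pos * p_noevent_pos
    if tn + fp == 0:
        raise ValueError("TN + FP is zero; specificity undefined")
    return tn / (tn + fp)


def nns(n_pos: float, n_total: float, p_event_by50_pos: float) -> float:
    """Number needed to screen to catch one pre-age-50 diagnosis.

    1 / ((n_pos / n_total) * p_event_by50_pos); report rounded to the
    nearest integer.
    """
    if n_pos > n_total:
        raise ValueError("n_pos cannot exceed n_total")
    if not 0.0 < p_event_by50_pos <= 1.0:
        raise ValueError("p_event_by50_pos must be in (0, 1]")
    denom = (n_pos / n_total) * p_event_by50_pos
    if denom == 0:
        raise ZeroDivisionError("no screen-positives: NNS is infinite")
    return 1.0 / denom


def nns_rounded(n_pos: float, n_total: float, p_event_by50_pos: float) -> int:
    return int(round(nns(n_pos, n_total, p_event_by50_pos)))


def false_negatives(brca_first_ages: Sequence[float | None],
                    flags: Sequence[bool]) -> int:
    """Women diagnosed before age 50 that the strategy did not flag."""
    if len(brca_first_ages) != len(flags):
        raise ValueError("ages and flags not aligned")
    return sum(
        1
        for age, hit in zip(brca_first_ages, flags)
        if age is not None and age < 50.0 and not hit
    )


# ---------------------------------------------------------------------------
# cohort-level strategy table
# ---------------------------------------------------------------------------

@dataclass
class StrategyMetrics:
    name: str
    n_pos: int
    frac_pos: float
    ppv: float
    specificity: float
    nns: float
    false_negatives: int
    n_with_fhx_among_pos: int
    frac_fhx_among_pos: float
    high_risk_label: bool = field(init=False)

    def __post_init__(self) -> None:
        # 20%-by-70 accumulated-risk threshold, used for labelling only
        self.high_risk_label = self.ppv >= HIGH_RISK_CUMINC_70


def evaluate_strategy(
    cohort: pd.DataFrame, strategy: StrategyDefinition
) -> StrategyMetrics:
    """Compute all metrics for one strategy on a per-participant frame.

    Required columns: ``carrier_genes`` (comma-joined, may be empty),
    ``percentile``, ``fhx_positive`` (bool), ``time`` (age at first
    breast-cancer code or censoring), ``event`` (bool),
    ``brca_first_age`` (NaN when undiagnosed).
    """
    flags = np.array(
        [
            assign_strategy(
                (g for g in genes.split(",") if g) if isinstance(genes, str) else genes,
                pct if pct == pct else None,
                bool(fhx),
                strategy,
            )
            for genes, pct, fhx in zip(
                cohort["carrier_genes"], cohort["percentile"], cohort["fhx_positive"]
            )
        ]
    )
    n = len(cohort)
    n_pos = int(flags.sum())
    t = cohort["time"].to_numpy(float)
    e = cohort["event"].to_numpy(bool)

    def km_cuminc(mask: np.ndarray, age: float) -> float:
        if mask.sum() == 0 or e[mask].sum() == 0:
            return 0.0
        res = KaplanMeier(t[mask], e[mask]).fit()
        return float(res.cumulative_incidence_at(age))

    p70_pos = km_cuminc(flags, 70.0)
    p70_neg = km_cuminc(~flags, 70.0)
    p50_pos = km_cuminc(flags, 50.0)
    spec = specificity(n - n_pos, p70_neg, n_pos, 1.0 - p70_pos) if n_pos < n else 0.0
    the_nns = (
        nns(n_pos, n, p50_pos) if n_pos > 0 and p50_pos > 0 else math.inf
    )
    ages = cohort["brca_first_age"].to_numpy(float)
    fn = false_negatives(
        [a if a == a else None for a in ages], list(flags)
    )
    fhx_pos = int((cohort["fhx_positive"].to_numpy(bool) & flags).sum())
    return StrategyMetrics(
        name=strategy.name,
        n_pos=n_pos,
        frac_pos=n_pos / n,
        ppv=ppv(p70_pos),
        specificity=spec,
        nns=the_nns,
        false_negatives=fn,
        n_with_fhx_among_pos=fhx_pos,
        frac_fhx_among_pos=fhx_pos / n_pos if n_pos else float("nan"),
    )


def strategy_table(
    cohort: pd.DataFrame,
    strategies: Sequence[StrategyDefinition] = DEFAULT_STRATEGIES,
) -> pd.DataFrame:
    """Strategy-comparison report (one row per strategy).

    Percentages are rounded to one decimal and NNS to an integer in the
    ``*_display`` columns; raw values are kept alongside.
    """
    rows = []
    for s in strategies:
        m = evaluate_strategy(cohort, s)
        rows.append(
            {
                "strategy": m.name,
                "n_pos": m.n_pos,
                "pct_of_population": round(100.0 * m.frac_pos, 1),
                "ppv_at70": m.ppv,
                "ppv_at70_display": round(100.0 * m.ppv, 1),
                "specificity": m.specificity,
                "specificity_display": round(100.0 * m.specificity, 1),
                "nns": m.nns,
                "nns_display": int(round(m.nns)) if math.isfinite(m.nns) else -1,
                "false_negatives": m.false_negatives,
                "n_with_fhx_among_pos": m.n_with_fhx_among_pos,
                "pct_fhx_among_pos": round(100.0 * m.frac_fhx_among_pos, 1)
                if m.n_pos
                else float("nan"),
                "high_risk_label": m.high_risk_label,
            }
        )
    return pd.DataFrame(rows)
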