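"""Family-history ascertainment-timing analysis.

A recorded family history of breast cancer (ICD-10-CM Z80.3) is only useful
for early screening if it is entered *before* the index diagnosis.  This
module extracts first qualifying code ages per phenotype from each
participant's EHR event stream, classifies the timing of the first
family-history code relative to the first breast-cancer code
(before / simultaneous / after, with "simultaneous" meaning within one week
before to one month after), tests whether the simultaneous enrichment is
specific to breast cancer versus comparator phenotypes, and builds the
bias-corrected cohort in which family-history-positive women whose code
arrived simultaneously with or after the diagnosis are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import DAYS_PER_YEAR, Participant

#: timing window (days, FHx minus BrCa) counted as "simultaneous":
#: one week before through one month after the first breast-cancer code
SIMULTANEOUS_WINDOW_DAYS = (-7.0, 30.0)

#: default phenotype definitions: name -> (include prefixes, exclude prefixes)
DEFAULT_PHENOTYPES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # first breast-cancer code; secondary neoplasms (C79.81) do not qualify
    "BrCa": (("C50", "D05", "Z85.3"), ()),
    "FHxBrCa": (("Z80.3",), ()),
    # family history of any non-breast condition: Z80-Z84 minus Z80.3
    "FHxOther": (("Z80", "Z81", "Z82", "Z83", "Z84"), ("Z80.3",)),
    "T1D": (("E10",), ()),
    "T2D": (("E11",), ()),
    "HTN": (("I10",), ()),
    "RA": (("M06",), ()),
}

BEFORE = "before"
SIMULTANEOUS = "simultaneous"
AFTER = "after"
FHX_ONLY = "fhx_only"
BRCA_ONLY = "brca_only"
NEITHER = "neither"


@dataclass
class CodeTimeline:
    participant_id: str
    first_age: dict[str, float | None]


@dataclass(frozen=True)
class TimingClass:
    delta_days: float | None
    category: str


def extract_first_codes(
    diagnosis_events: Sequence[tuple[str, float]],
    phenotypes: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
    participant_id: str = "",
) -> CodeTimeline:
    """Earliest qualifying code age per phenotype definition.

    A code qualifies if it starts with any include prefix and with no
    exclude prefix (exclusions applied first, e.g. Z80.3 is removed from
    the other-family-history set).
    """
    defs = DEFAULT_PHENOTYPES if phenotypes is None else phenotypes
    first: dict[str, float | None] = {}
    for name, spec in defs.items():
        include, exclude = spec
        ages = [
            age
            for code, age in diagnosis_events
            if not any(code.startswith(x) for x in exclude)
            and any(code.startswith(p) for p in include)
        ]
        first[name] = min(ages) if ages else None
    return CodeTimeline(participant_id=participant_id, first_age=first)


def classify_timing(
    timeline: CodeTimeline,
    brca: str = "BrCa",
    fhx: str = "FHxBrCa",
    window_days: tuple[float, float] = SIMULTANEOUS_WINDOW_DAYS,
) -> TimingClass:
    """Timing of the first family-history code relative to the diagnosis."""
    brca_age = timeline.first_age.get(brca)
    fhx_age = timeline.first_age.get(fhx)
    if brca_age is None and fhx_age is None:
        return TimingClass(None, NEITHER)
    if brca_age is None:
        return TimingClass(None, FHX_ONLY)
    if fhx_age is None:
        return TimingClass(None, BRCA_ONLY)
    delta = (fhx_age - brca_age) * DAYS_PER_YEAR
    lo, hi = window_days
    if delta < lo:
        category = BEFORE
    elif delta > hi:
        category = AFTER
    else:
        category = SIMULTANEOUS
    return TimingClass(float(delta), category)


def timing_report(
    participants: Iterable[Participant],
    phenotypes=None,
    brca: str = "BrCa",
    fhx: str = "FHxBrCa",
    window_days: tuple[float, float] = SIMULTANEOUS_WINDOW_DAYS,
) -> pd.DataFrame:
    """Per-participant timing category and day offset."""
    rows = []
    for p in participants:
        tl = extract_first_codes(p.diagnosis_events, phenotypes, p.id)
        tc = classify_timing(tl, brca=brca, fhx=fhx, window_days=window_days)
        rows.append(
            {
                "participant_id": p.id,
                "brca_first_age": tl.first_age.get(brca),
                "fhx_first_age": tl.first_age.get(fhx),
                "delta_days": tc.delta_days,
                "category": tc.category,
            }
        )
    return pd.DataFrame(rows)


def timing_counts(report: pd.DataFrame) -> dict[str, int]:
    counts = report["category"].value_counts().to_dict()
    return {
        c: int(counts.get(c, 0))
        for c in (BEFORE, SIMULTANEOUS, AFTER, FHX_ONLY, BRCA_ONLY, NEITHER)
    }


def enrichment_test(
    counts_brca: tuple[int, int], counts_comparator: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) comparing the
    simultaneous-vs-not split around breast cancer against a comparator
    phenotype.

    Parameters are (n_simultaneous, n_not) pairs.
    """
    table = np.array([counts_brca, counts_comparator], dtype=float)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    res = chi2_contingency(table, correction=False)
    expected = res.expected_freq
    if np.any(expected < 1):
        import warnings

        warnings.warn("expected cell count below 1; chi-square unreliable",
                      stacklevel=2)
    return float(res.statistic), float(res.pvalue)


def delta_histogram(report: pd.DataFrame, bin_days: float = 10.0,
                    clip_days: float = 1000.0) -> pd.DataFrame:
    """Histogram of FHx-minus-diagnosis day offsets (plot-ready)."""
    deltas = report["delta_days"].dropna().clip(-clip_days, clip_days)
    edges = np.arange(-clip_days, clip_days + bin_days, bin_days)
    hist, _ = np.histogram(deltas, bins=edges)
    return pd.DataFrame({"bin_left_days": edges[:-1], "count": hist})


def debias_cohort(
    participants: Sequence[Participant],
    phenotypes=None,
    window_days: tuple[float, float] = SIMULTANEOUS_WINDOW_DAYS,
) -> list[Participant]:
    """Remove family-history-positive women whose first family-history code
    was simultaneous with or after the first breast-cancer code.

    Everyone else (family-history-negative women, women with the code
    strictly before diagnosis, women without a diagnosis) is retained
    untouched.
    """
    kept = []
    for p in participants:
        tl = extract_first_codes(p.diagnosis_events, phenotypes, p.id)
        tc = classify_timing(tl, window_days=window_days)
        if tc.category in (SIMULTANEOUS, AFTER):
            continue
        kept.append(p)
    return kept
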