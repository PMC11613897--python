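"""Synthetic EHR + genotype cohort generator.

Generates cohorts of women with the statistical structure the downstream
risk-stratification analysis assumes: a bimodal age distribution, per-gene
Bernoulli carrier status, breast-cancer onset from a proportional-hazards
model with a piecewise-constant baseline hazard calibrated to a target
cumulative incidence at age 70, a standardized polygenic score whose effect
is calibrated to a target top-decile hazard ratio, and family-history codes
whose timing relative to the first breast-cancer code follows a configured
before/simultaneous/after mixture (the ascertainment-bias mechanism).

Breast-cancer status is *not* stored on the participant; it is carried only
through dated ICD-10-CM diagnosis events, exactly as an EHR would, so the
downstream phenotype-extraction code is exercised for real.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .config import GENES, GROUPS, SimConfig

DAYS_PER_YEAR = 365.25

#: ICD-10-CM codes emitted by the generator
BRCA_CODE = "C50.911"
FHX_BRCA_CODE = "Z80.3"
OTHER_FHX_CODE = "Z82.49"


@dataclass
class Participant:
    """One woman: EHR timeline plus genetic attachments."""

    id: str
    genetic_group: str
    current_age: float
    ehr_start_age: float
    ehr_end_age: float
    diagnosis_events: list[tuple[str, float]] = field(default_factory=list)
    carrier_genes: frozenset[str] = frozenset()
    prs_raw: float = 0.0
    fhx_first_code_age: float | None = None

    def validate(self) -> None:
        if self.genetic_group not in GROUPS:
            raise ValueError(f"{self.id}: unknown genetic group {self.genetic_group!r}")
        if not (self.ehr_start_age <= self.ehr_end_age <= self.current_age):
            raise ValueError(
                f"{self.id}: require ehr_start_age <= ehr_end_age <= current_age"
            )
        for code, age in self.diagnosis_events:
            if not (0.0 <= age <= self.current_age):
                raise ValueError(f"{self.id}: event {code} at age {age} out of range")
        if set(self.carrier_genes) - set(GENES):
            raise ValueError(f"{self.id}: carrier genes outside the 5-gene panel")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _truncnorm_exp_mean(beta: float, a: float, b: float) -> float:
    """E[exp(beta*Z) | a < Z < b] for Z ~ N(0,1) (closed form)."""
    denom = norm.cdf(b) - norm.cdf(a)
    return float(
        np.exp(0.5 * beta**2) * (norm.cdf(b - beta) - norm.cdf(a - beta)) / denom
    )


def calibrate_prs_beta(top10_hr: float) -> float:
    """Log-hazard per PRS standard deviation reproducing the top-decile HR.

    Solves E[e^{bZ} | Z > q90] / E[e^{bZ} | q30 < Z < q70] = top10_hr,
    i.e. the hazard of the top decile relative to the middle 40% of the
    standardized score distribution.
    """
    if top10_hr <= 0:
        raise ValueError("top-decile hazard ratio must be positive")
    if abs(top10_hr - 1.0) < 1e-12:
        return 0.0
    q90, q30, q70 = norm.ppf([0.90, 0.30, 0.70])

    def f(b: float) -> float:
        return (
            _truncnorm_exp_mean(b, q90, np.inf)
            / _truncnorm_exp_mean(b, q30, q70)
            - top10_hr
        )

    lo, hi = (0.0, 5.0) if top10_hr > 1 else (-5.0, 0.0)
    return float(brentq(f, lo, hi, xtol=1e-12))


def _band_cumhaz(edges: np.ndarray, rates: np.ndarray, t: float) -> float:
    """Integral of the piecewise-constant relative hazard up to age t."""
    widths = np.minimum(np.maximum(t - edges[:-1], 0.0), np.diff(edges))
    return float(np.sum(widths * rates))


def calibrate_baseline_scale(config: SimConfig, beta: float) -> float:
    """Global hazard scale s such that the carrier-free, middle-PRS stratum
    reaches the configured cumulative incidence at age 70.

    Averages 1 - exp(-s * H_rel(70) * e^{beta z}) over z in the middle 40%
    of a standard normal (Gauss-Legendre over the truncated band) and root
    finds on s.
    """
    config.validate()
    edges = np.asarray(config.hazard_band_edges, dtype=float)
    rates = np.asarray(config.hazard_band_rates, dtype=float)
    h70 = _band_cumhaz(edges, rates, 70.0)
    if h70 <= 0:
        raise ValueError("relative cumulative hazard at 70 is zero; cannot calibrate")
    target = config.baseline_cuminc_70

    q30, q70 = norm.ppf([0.30, 0.70])
    # quadrature nodes in probability space -> z space (uniform density there)
    p = np.linspace(0.302, 0.698, 99)
    z = norm.ppf(p)

    def mean_cuminc(s: float) -> float:
        return float(np.mean(1.0 - np.exp(-s * h70 * np.exp(beta * z))))

    lo, hi = 1e-12, 1.0
    while mean_cuminc(hi) < target:
        hi *= 10.0
        if hi > 1e6:
            raise ValueError("baseline calibration infeasible for target incidence")
    return float(brentq(lambda s: mean_cuminc(s) - target, lo, hi, xtol=1e-14))


def _invert_cumhaz(edges: np.ndarray, rates: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Ages at which the piecewise-constant cumulative hazard reaches targets.

    Targets beyond the total integral map to +inf (event never occurs).
    """
    widths = np.diff(edges)
    seg = widths * rates
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.full(targets.shape, np.inf)
    for i in range(len(rates)):
        mask = (targets > cum[i]) & (targets <= cum[i + 1]) & (rates[i] > 0)
        out[mask] = edges[i] + (targets[mask] - cum[i]) / rates[i]
    out[targets <= 0] = edges[0]
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> list[Participant]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_women

    # genetic-similarity groups
    group_names = [g for g in GROUPS if g in config.group_proportions]
    probs = np.array([config.group_proportions[g] for g in group_names])
    group_idx = rng.choice(len(group_names), size=n, p=probs / probs.sum())
    groups = np.array(group_names, dtype=object)[group_idx]

    # bimodal current age, clipped to bounds
    weights = np.array([c[0] for c in config.age_components])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    means = np.array([c[1] for c in config.age_components])[comp]
    sds = np.array([c[2] for c in config.age_components])[comp]
    current_age = np.clip(rng.normal(means, sds), *config.age_bounds)

    # EHR span
    span = np.clip(rng.normal(*config.ehr_span_years, size=n), 0.5, None)
    ehr_end = current_age.copy()
    ehr_start = np.maximum(18.0, ehr_end - span)
    ehr_start = np.minimum(ehr_start, ehr_end)

    # carriers: independent Bernoulli per gene
    carrier = {
        gene: rng.random(n) < config.gene_carrier_counts.get(gene, 0) / n
        for gene in GENES
    }
    gene_mult = np.ones(n)
    for gene in GENES:
        hr = config.gene_hr.get(gene, 1.0)
        # multi-gene carriers take the largest multiplier
        gene_mult = np.where(
            carrier[gene], np.maximum(gene_mult, hr), gene_mult
        )

    # standardized polygenic score and raw score on a group-shifted scale
    z = rng.standard_normal(n)
    group_mean = np.array(
        [config.prs_group_means.get(g, 0.0) for g in groups], dtype=float
    )
    prs_raw = group_mean + z

    # onset ages from the proportional-hazards model
    beta = calibrate_prs_beta(config.prs_top10_hr)
    scale = calibrate_baseline_scale(config, beta)
    edges = np.asarray(config.hazard_band_edges, dtype=float)
    rates = np.asarray(config.hazard_band_rates, dtype=float)
    mult = scale * gene_mult * np.exp(beta * z)
    u = rng.random(n)
    onset = _invert_cumhaz(edges, rates, -np.log(u) / mult)
    affected = onset <= current_age
    onset_age = np.where(affected, onset, np.nan)

    # family-history indicator: logistic in carrier status and z
    any_carrier = np.zeros(n, dtype=bool)
    for gene in GENES:
        any_carrier |= carrier[gene]
    eta = (
        np.log(config.fhx_carrier_or) * any_carrier.astype(float)
        + config.fhx_prs_beta * z
    )

    def prevalence(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + eta)))))

    if config.fhx_prevalence in (0.0, 1.0):
        fhx = np.full(n, bool(config.fhx_prevalence))
    else:
        alpha = brentq(
            lambda a: prevalence(a) - config.fhx_prevalence, -20.0, 10.0, xtol=1e-10
        )
        fhx = rng.random(n) < 1.0 / (1.0 + np.exp(-(alpha + eta)))

    # family-history code age
    fhx_age = np.full(n, np.nan)
    aff_fhx = fhx & affected
    if aff_fhx.any():
        cat = rng.choice(3, size=int(aff_fhx.sum()), p=np.array(config.fhx_timing_mix))
        delta_days = np.empty(cat.shape)
        delta_days[cat == 0] = -rng.uniform(8.0, 15 * DAYS_PER_YEAR, size=(cat == 0).sum())
        delta_days[cat == 1] = rng.uniform(-7.0, 30.0, size=(cat == 1).sum())
        delta_days[cat == 2] = rng.uniform(31.0, 15 * DAYS_PER_YEAR, size=(cat == 2).sum())
        ages = onset_age[aff_fhx] + delta_days / DAYS_PER_YEAR
        ages = np.clip(ages, 18.0, current_age[aff_fhx])
        fhx_age[aff_fhx] = ages
    unaff_fhx = fhx & ~affected
    if unaff_fhx.any():
        lo = np.maximum(18.0, ehr_start[unaff_fhx])
        hi = current_age[unaff_fhx]
        fhx_age[unaff_fhx] = lo + rng.random(int(unaff_fhx.sum())) * np.maximum(hi - lo, 0.0)

    # unrelated comparator diagnoses and non-breast family-history codes
    comparators = {
        code: (rng.random(n) < rate, rng.random(n))
        for code, rate in config.comparator_rates.items()
    }
    other_fhx = rng.random(n) < config.other_fhx_rate
    other_fhx_age = 18.0 + rng.random(n) * np.maximum(current_age - 18.0, 0.0)

    width = len(str(n))
    participants: list[Participant] = []
    for i in range(n):
        events: list[tuple[str, float]] = []
        if affected[i]:
            events.append((BRCA_CODE, float(onset_age[i])))
        if fhx[i] and np.isfinite(fhx_age[i]):
            events.append((FHX_BRCA_CODE, float(fhx_age[i])))
        for code, (has, frac) in comparators.items():
            if has[i] and current_age[i] > 30.0:
                events.append(
                    (code, float(30.0 + frac[i] * (current_age[i] - 30.0)))
                )
        if other_fhx[i]:
            events.append((OTHER_FHX_CODE, float(other_fhx_age[i])))
        events.sort(key=lambda e: e[1])
        genes = frozenset(g for g in GENES if carrier[g][i])
        p = Participant(
            id=f"P{i + 1:0{width}d}",
            genetic_group=str(groups[i]),
            current_age=float(current_age[i]),
            ehr_start_age=float(ehr_start[i]),
            ehr_end_age=float(ehr_end[i]),
            diagnosis_events=events,
            carrier_genes=genes,
            prs_raw=float(prs_raw[i]),
            fhx_first_code_age=float(fhx_age[i]) if fhx[i] and np.isfinite(fhx_age[i]) else None,
        )
        participants.append(p)
    return participants


# ---------------------------------------------------------------------------
# cohort I/O (TSV; diagnosis events as code@age;code@age)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "id",
    "genetic_group",
    "current_age",
    "ehr_start_age",
    "ehr_end_age",
    "diagnosis_events",
    "carrier_genes",
    "prs_raw",
    "fhx_first_code_age",
]


def write_cohort(participants: Iterable[Participant], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for p in participants:
            p.validate()
            events = ";".join(f"{code}@{age:.6f}" for code, age in p.diagnosis_events)
            genes = ",".join(sorted(p.carrier_genes))
            fhx = "" if p.fhx_first_code_age is None else f"{p.fhx_first_code_age:.6f}"
            w.writerow(
                [
                    p.id,
                    p.genetic_group,
                    f"{p.current_age:.6f}",
                    f"{p.ehr_start_age:.6f}",
                    f"{p.ehr_end_age:.6f}",
                    events,
                    genes,
                    f"{p.prs_raw:.6f}",
                    fhx,
                ]
            )


def read_cohort(path: str | Path) -> list[Participant]:
    participants: list[Participant] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                events = []
                if row[5]:
                    for item in row[5].split(";"):
                        code, age = item.rsplit("@", 1)
                        events.append((code, float(age)))
                genes = frozenset(g for g in row[6].split(",") if g)
                p = Participant(
                    id=row[0],
                    genetic_group=row[1],
                    current_age=float(row[2]),
                    ehr_start_age=float(row[3]),
                    ehr_end_age=float(row[4]),
                    diagnosis_events=events,
                    carrier_genes=genes,
                    prs_raw=float(row[7]),
                    fhx_first_code_age=float(row[8]) if row[8] else None,
                )
                p.validate()
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            participants.append(p)
    return participants


def cohort_to_frame(participants: Sequence[Participant]):
    """Flat pandas view of a cohort (events stay encoded on the participant)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [p.id for p in participants],
            "genetic_group": [p.genetic_group for p in participants],
            "current_age": [p.current_age for p in participants],
            "prs_raw": [p.prs_raw for p in participants],
            "carrier_genes": [",".join(sorted(p.carrier_genes)) for p in participants],
            "fhx_first_code_age": [p.fhx_first_code_age for p in participants],
        }
    )
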