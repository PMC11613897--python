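"""Simulation and analysis configuration.

:class:`SimConfig` holds every knob of the synthetic-cohort generator: cohort
size, genetic-similarity group mix, per-gene carrier counts and hazard
multipliers, the polygenic-score effect (expressed as the top-decile hazard
ratio it must reproduce), baseline cumulative incidence, family-history
prevalence/association, and the timing mixture that drives the
ascertainment-bias analysis.  Defaults describe a ~25.6k-woman screening
cohort with 410 pathogenic-variant carriers across BRCA1, BRCA2, PALB2, ATM
and CHEK2.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

GENES = ("BRCA1", "BRCA2", "PALB2", "ATM", "CHEK2")
GROUPS = ("Africa", "Americas", "EastAsia", "Europe", "Other", "SouthAsia")

#: analysis-group precedence for multi-gene carriers
GENE_PRECEDENCE = {g: i for i, g in enumerate(GENES)}

#: accumulated-risk threshold labelling a stratum "high risk" (20% by age 70)
HIGH_RISK_CUMINC_70 = 0.20


def _default_group_proportions() -> dict[str, float]:
    counts = {
        "Africa": 499,
        "Americas": 3728,
        "EastAsia": 832,
        "Europe": 19484,
        "Other": 929,
        "SouthAsia": 119,
    }
    total = sum(counts.values())
    return {g: n / total for g, n in counts.items()}


def _default_carrier_counts() -> dict[str, float]:
    return {"BRCA1": 70, "BRCA2": 89, "PALB2": 39, "ATM": 95, "CHEK2": 117}


def _default_gene_hr() -> dict[str, float]:
    # group-level penetrance multipliers: the analysis pools BRCA1/BRCA2/PALB2
    # and ATM/CHEK2, so the default generative hazard is the group value each
    # pooled Cox fit should recover.  Per-gene values (BRCA1 16.2, BRCA2 8.5,
    # PALB2 6.3, ATM 4.3, CHEK2 2.6) are a drop-in alternative configuration.
    return {"BRCA1": 10.4, "BRCA2": 10.4, "PALB2": 10.4, "ATM": 3.4, "CHEK2": 3.4}


@dataclass
class SimConfig:
    """Parameters of the synthetic EHR + genotype cohort.

    The defaults target the statistical structure of a large all-comer
    population-screening cohort of women: bimodal age structure, ~1.6%
    pathogenic-variant carriers, 9.3% baseline cumulative incidence of
    breast cancer by age 70, a top-decile polygenic hazard ratio of 2.4,
    6.9% prevalence of a recorded family history with carrier odds ratio
    3.5, and a 22/30/48 before/simultaneous/after code-timing mixture.
    """

    n_women: int = 25_591
    group_proportions: dict[str, float] = field(
        default_factory=_default_group_proportions
    )
    gene_carrier_counts: dict[str, float] = field(
        default_factory=_default_carrier_counts
    )
    gene_hr: dict[str, float] = field(default_factory=_default_gene_hr)
    prs_top10_hr: float = 2.4
    baseline_cuminc_70: float = 0.093
    fhx_prevalence: float = 0.069
    fhx_carrier_or: float = 3.5
    #: log-odds of family history per PRS standard deviation (the association
    #: is reported as positive and significant; its size is a free choice)
    fhx_prs_beta: float = 0.15
    fhx_timing_mix: tuple[float, float, float] = (0.22, 0.30, 0.48)
    #: (mean, sd) of the EHR longitudinal span in years
    ehr_span_years: tuple[float, float] = (12.0, 5.0)
    #: bimodal current-age structure: (weight, mean, sd) per normal component
    age_components: tuple[tuple[float, float, float], ...] = (
        (0.72, 46.0, 11.0),
        (0.28, 74.0, 7.0),
    )
    age_bounds: tuple[float, float] = (19.0, 89.0)
    #: piecewise-constant baseline-hazard age bands and relative rates
    hazard_band_edges: tuple[float, ...] = (0.0, 40.0, 50.0, 60.0, 70.0, 90.0)
    hazard_band_rates: tuple[float, ...] = (0.1, 1.0, 1.4, 1.8, 2.0)
    #: per-group mean of the raw polygenic score (sd fixed at 1 within group)
    prs_group_means: dict[str, float] = field(
        default_factory=lambda: {
            "Africa": 0.30,
            "Americas": 0.10,
            "EastAsia": 0.05,
            "Europe": 0.0,
            "Other": 0.05,
            "SouthAsia": 0.10,
        }
    )
    #: marginal rates of unrelated comparator diagnoses (EHR QC phenotypes)
    comparator_rates: dict[str, float] = field(
        default_factory=lambda: {"I10": 0.35, "E11": 0.12}
    )
    #: fraction of women with a family-history code for a non-breast condition
    other_fhx_rate: float = 0.268
    seed: int = 0

    def validate(self) -> None:
        if self.n_women <= 0:
            raise ValueError("n_women must be positive")
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if set(self.group_proportions) - set(GROUPS):
            raise ValueError(f"unknown genetic-similarity group in {self.group_proportions}")
        if set(self.gene_carrier_counts) - set(GENES):
            raise ValueError("gene_carrier_counts restricted to the 5-gene panel")
        for gene, n in self.gene_carrier_counts.items():
            if n < 0 or n > self.n_women:
                raise ValueError(f"carrier count for {gene} out of range")
        for gene, hr in self.gene_hr.items():
            if hr <= 0 or not math.isfinite(hr):
                raise ValueError(f"hazard multiplier for {gene} must be positive")
        if self.prs_top10_hr <= 0:
            raise ValueError("prs_top10_hr must be positive")
        for name in ("baseline_cuminc_70", "fhx_prevalence", "other_fhx_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.baseline_cuminc_70 >= 1.0:
            raise ValueError("baseline_cuminc_70 >= 1 is not a calibratable incidence")
        if self.fhx_carrier_or <= 0:
            raise ValueError("fhx_carrier_or must be positive")
        if abs(sum(self.fhx_timing_mix) - 1.0) > 1e-9 or any(
            p < 0 for p in self.fhx_timing_mix
        ):
            raise ValueError("fhx_timing_mix must be a probability triple summing to 1")
        if len(self.hazard_band_edges) != len(self.hazard_band_rates) + 1:
            raise ValueError("hazard bands: need one more edge than rate")
        if any(r < 0 for r in self.hazard_band_rates):
            raise ValueError("hazard band rates must be non-negative")
        if list(self.hazard_band_edges) != sorted(self.hazard_band_edges):
            raise ValueError("hazard band edges must be increasing")
        w = sum(c[0] for c in self.age_components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("age component weights must sum to 1")

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(d)
        for name in ("fhx_timing_mix", "ehr_span_years", "age_bounds",
                     "hazard_band_edges", "hazard_band_rates"):
            if name in kwargs and isinstance(kwargs[name], Sequence):
                kwargs[name] = tuple(kwargs[name])
        if "age_components" in kwargs:
            kwargs["age_components"] = tuple(
                tuple(c) for c in kwargs["age_components"]
            )
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML or TOML file."""
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(data)


def save_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
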