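"""Cohort-level risk-stratification model.

:class:`RiskStratification` is the high-level entry point: built from a
cohort of participants, its :meth:`~RiskStratification.fit` derives the
survival frame from EHR events, assigns group-wise PRS percentiles, fits
the Cox hazard-ratio models (per-gene, grouped monogenic, top-decile
polygenic, family history), reads Kaplan-Meier cumulative incidences at
age 70 per stratum, evaluates the screening strategies, and runs the
family-history association tests.  The returned results object carries all
of these with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import assoc, fhx, prs, screening
from .cohort import Participant
from .config import GENES
from .survival import CoxPH, CoxPHResults, KaplanMeier
from .variants import analysis_gene

#: "average polygenic risk" reference band of group percentiles
MIDDLE_PRS_BAND = (30.0, 70.0)


def build_analysis_frame(
    participants: Sequence[Participant], fhx_mode: str = "any_time"
) -> pd.DataFrame:
    """Tidy per-participant frame for survival and screening analyses.

    ``fhx_mode`` controls the family-history flag: ``any_time`` counts a
    Z80.3 code whenever recorded (best case); ``pre_diagnosis`` counts it
    only when it clearly precedes the first breast-cancer code (worse
    case).
    """
    if fhx_mode not in ("any_time", "pre_diagnosis"):
        raise ValueError("fhx_mode must be 'any_time' or 'pre_diagnosis'")
    rows = []
    for p in participants:
        tl = fhx.extract_first_codes(p.diagnosis_events, participant_id=p.id)
        tc = fhx.classify_timing(tl)
        brca_age = tl.first_age.get("BrCa")
        fhx_age = tl.first_age.get("FHxBrCa")
        if fhx_mode == "any_time":
            fhx_pos = fhx_age is not None
        else:
            fhx_pos = tc.category in (fhx.BEFORE, fhx.FHX_ONLY)
        rows.append(
            {
                "participant_id": p.id,
                "genetic_group": p.genetic_group,
                "current_age": p.current_age,
                "event": brca_age is not None,
                "time": brca_age if brca_age is not None else p.current_age,
                "brca_first_age": brca_age if brca_age is not None else np.nan,
                "carrier_genes": ",".join(sorted(p.carrier_genes)),
                "analysis_gene": analysis_gene(p.carrier_genes) or "",
                "raw_score": p.prs_raw,
                "fhx_positive": fhx_pos,
                "fhx_first_age": fhx_age if fhx_age is not None else np.nan,
                "timing_category": tc.category,
            }
        )
    frame = pd.DataFrame(rows)
    frame = prs.assign_percentiles(frame)
    return frame


@dataclass
class RiskStratificationResults:
    frame: pd.DataFrame
    gene_hr: pd.DataFrame
    grouped_hr: CoxPHResults
    prs_top10_hr: CoxPHResults
    fhx_hr: CoxPHResults | None
    km_cuminc70: dict[str, float]
    strategy_report: pd.DataFrame
    associations: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """One-row-per-quantity overview of the fitted analysis."""
        rows = []
        for gene in self.gene_hr.index:
            rows.append(
                {
                    "quantity": f"HR {gene} carrier vs non-carrier",
                    "value": self.gene_hr.loc[gene, "hr"],
                    "ci_low": self.gene_hr.loc[gene, "hr_lower"],
                    "ci_high": self.gene_hr.loc[gene, "hr_upper"],
                }
            )
        gs = self.grouped_hr.summary()
        for name in gs.index:
            rows.append(
                {
                    "quantity": f"HR {name}",
                    "value": gs.loc[name, "hr"],
                    "ci_low": gs.loc[name, "hr_lower"],
                    "ci_high": gs.loc[name, "hr_upper"],
                }
            )
        ps = self.prs_top10_hr.summary().iloc[0]
        rows.append(
            {
                "quantity": "HR top-10% PRS vs average (non-carriers)",
                "value": ps["hr"],
                "ci_low": ps["hr_lower"],
                "ci_high": ps["hr_upper"],
            }
        )
        if self.fhx_hr is not None:
            fs = self.fhx_hr.summary().iloc[0]
            rows.append(
                {
                    "quantity": "HR family history vs none",
                    "value": fs["hr"],
                    "ci_low": fs["hr_lower"],
                    "ci_high": fs["hr_upper"],
                }
            )
        for name, v in self.km_cuminc70.items():
            rows.append(
                {
                    "quantity": f"cumulative incidence by 70: {name}",
                    "value": v,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
        return pd.DataFrame(rows)


class RiskStratification:
    """Risk-stratification analysis over one cohort."""

    def __init__(self, frame: pd.DataFrame):
        required = {
            "time", "event", "carrier_genes", "analysis_gene",
            "percentile", "fhx_positive", "brca_first_age",
        }
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"analysis frame missing columns {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_participants(
        cls, participants: Sequence[Participant], fhx_mode: str = "any_time"
    ) -> "RiskStratification":
        return cls(build_analysis_frame(participants, fhx_mode=fhx_mode))

    # -- strata -----------------------------------------------------------

    def _noncarrier(self) -> pd.Series:
        return self.frame["analysis_gene"] == ""

    def _middle_prs(self) -> pd.Series:
        lo, hi = MIDDLE_PRS_BAND
        return (self.frame["percentile"] > lo) & (self.frame["percentile"] <= hi)

    def _top_prs(self, fraction: float = 0.10) -> pd.Series:
        return pd.Series(
            prs.top_fraction_flags(self.frame["percentile"], fraction),
            index=self.frame.index,
        )

    # -- fits -------------------------------------------------------------

    def _drop_eventless(self, X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        """Remove indicator columns whose members have no events.

        A stratum with carriers but zero events has a monotone partial
        likelihood (HR estimate 0, coefficient at -infinity), so it cannot
        be fitted; it is reported as NaN instead.
        """
        events = self.frame["event"].to_numpy(bool)
        dropped = [
            c for c in X.columns if not events[X[c].to_numpy(bool)].any()
        ]
        if dropped:
            warnings.warn(
                f"no events among members of {dropped}; "
                "hazard ratio not estimable (reported as NaN)",
                stacklevel=3,
            )
        return X.drop(columns=dropped), dropped

    def fit_gene_hrs(self) -> pd.DataFrame:
        """One Cox fit with an indicator per analysis-group gene
        (reference: non-carriers)."""
        df = self.frame
        X = pd.DataFrame(
            {g: (df["analysis_gene"] == g).astype(float) for g in GENES
             if (df["analysis_gene"] == g).any()}
        )
        X, dropped = self._drop_eventless(X)
        if X.empty:
            raise ValueError("no gene stratum with events; cannot fit")
        res = CoxPH(df["time"], df["event"], X).fit()
        out = res.summary()
        if dropped:
            out = pd.concat(
                [out, pd.DataFrame(np.nan, index=dropped, columns=out.columns)]
            )
        return out

    def fit_grouped_hrs(self) -> CoxPHResults:
        """Monogenic/polygenic grouping: BRCA1/BRCA2/PALB2 carriers,
        ATM/CHEK2 carriers, top-10% PRS non-carriers, vs everyone else."""
        df = self.frame
        high_pen = df["analysis_gene"].isin(["BRCA1", "BRCA2", "PALB2"])
        mid_pen = df["analysis_gene"].isin(["ATM", "CHEK2"])
        top10 = self._top_prs(0.10) & self._noncarrier()
        X = pd.DataFrame(
            {
                "BRCA1_BRCA2_PALB2": high_pen.astype(float),
                "ATM_CHEK2": mid_pen.astype(float),
                "top10_PRS_noncarrier": top10.astype(float),
            }
        )
        X, _ = self._drop_eventless(X)
        return CoxPH(df["time"], df["event"], X).fit()

    def fit_prs_top10_hr(self) -> CoxPHResults:
        """Top-decile vs average-PRS hazard among non-carriers only."""
        df = self.frame
        keep = self._noncarrier() & (self._top_prs(0.10) | self._middle_prs())
        sub = df[keep]
        X = pd.DataFrame(
            {"top10_PRS": self._top_prs(0.10)[keep].astype(float).to_numpy()},
            index=sub.index,
        )
        return CoxPH(sub["time"], sub["event"], X).fit()

    def fit_fhx_hr(self) -> CoxPHResults | None:
        df = self.frame
        if df["fhx_positive"].nunique() < 2:
            return None
        X = pd.DataFrame({"fhx": df["fhx_positive"].astype(float)})
        return CoxPH(df["time"], df["event"], X).fit()

    def km_readouts(self) -> dict[str, float]:
        df = self.frame

        def cuminc70(mask: pd.Series) -> float:
            sub = df[mask]
            if sub.empty or not sub["event"].any():
                return float("nan")
            return float(
                KaplanMeier(sub["time"], sub["event"]).fit().cumulative_incidence_at(70.0)
            )

        out = {
            "non-carrier, average PRS": cuminc70(self._noncarrier() & self._middle_prs()),
            "non-carrier": cuminc70(self._noncarrier()),
            "top-10% PRS non-carrier": cuminc70(self._top_prs(0.10) & self._noncarrier()),
        }
        for g in GENES:
            mask = df["analysis_gene"] == g
            if mask.any():
                out[f"{g} carrier"] = cuminc70(mask)
        atm_chek2 = df["analysis_gene"].isin(["ATM", "CHEK2"])
        out["ATM/CHEK2 carrier, top-50% PRS"] = cuminc70(atm_chek2 & self._top_prs(0.50))
        out["ATM/CHEK2 carrier, bottom-50% PRS"] = cuminc70(
            atm_chek2 & ~self._top_prs(0.50)
        )
        return out

    def association_tests(self, group: str = "Europe") -> dict:
        """Carrier/FHx/PRS correlations among undiagnosed women of the
        largest genetic-similarity group (standardized raw scores)."""
        df = self.frame
        keep = (~df["event"]) & (df["genetic_group"] == group)
        sub = df[keep].copy()
        if sub.empty:
            return {}
        sub["z"] = (sub["raw_score"] - sub["raw_score"].mean()) / sub[
            "raw_score"
        ].std(ddof=1)
        carrier = (sub["analysis_gene"] != "").to_numpy()
        fhx_pos = sub["fhx_positive"].to_numpy(bool)
        out = {"carrier_vs_fhx": assoc.carrier_fhx_association(carrier, fhx_pos)}
        if fhx_pos.any() and (~fhx_pos).any():
            t, dfree, p = assoc.welch_t(sub["z"][fhx_pos], sub["z"][~fhx_pos])
            out["prs_by_fhx"] = {"t": t, "df": dfree, "p_value": p}
        if carrier.any() and (~carrier).any():
            t, dfree, p = assoc.welch_t(sub["z"][carrier], sub["z"][~carrier])
            out["prs_by_carrier"] = {"t": t, "df": dfree, "p_value": p}
        return out

    def fit(
        self,
        strategies: Sequence[screening.StrategyDefinition] = screening.DEFAULT_STRATEGIES,
    ) -> RiskStratificationResults:
        return RiskStratificationResults(
            frame=self.frame,
            gene_hr=self.fit_gene_hrs(),
            grouped_hr=self.fit_grouped_hrs(),
            prs_top10_hr=self.fit_prs_top10_hr(),
            fhx_hr=self.fit_fhx_hr(),
            km_cuminc70=self.km_readouts(),
            strategy_report=screening.strategy_table(self.frame, strategies),
            associations=self.association_tests(),
        )
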