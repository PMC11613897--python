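"""Polygenic risk score engine.

Computes a linear PRS (weighted sum of effect-allele dosages over ~300
common SNVs) per participant, with a three-level dosage fallback:
imputed genotype probabilities (GP), then hard genotype calls (GT), then
twice the reference allele frequency of the participant's closest
genetic-similarity group.  Raw scores are then converted to percentiles by
ranking *within* each genetic-similarity group, after which the groups are
concatenated back into one cohort so that "top X%" always means the top of
a participant's own group distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

#: fraction of participants allowed to lack both GP and GT before a score
#: variant is dropped for poor callability
DEFAULT_CALLABILITY_MAX_MISSING = 0.10


@dataclass
class PrsModel:
    """A PGS-Catalog-style linear scoring model."""

    entries: pd.DataFrame  # variant_id, effect_allele, other_allele, effect_weight
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        required = {"variant_id", "effect_allele", "other_allele", "effect_weight"}
        if not required <= set(self.entries.columns):
            raise ValueError(f"scoring model needs columns {sorted(required)}")
        if self.entries["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id in scoring model")
        if not np.all(np.isfinite(self.entries["effect_weight"].astype(float))):
            raise ValueError("non-finite effect weight")

    def __len__(self) -> int:
        return len(self.entries)


def read_scoring_file(path: str | Path) -> PrsModel:
    """Parse a PGS Catalog flat scoring file (tab-separated, ``#`` headers)."""
    build = "GRCh38"
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    for line in header_lines:
        if "genome_build" in line.lower():
            build = line.split("=")[-1].strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "rsID" in df.columns and "variant_id" not in df.columns:
        df = df.rename(columns={"rsID": "variant_id"})
    df["effect_weight"] = df["effect_weight"].astype(float)
    cols = ["variant_id", "effect_allele", "other_allele", "effect_weight"]
    return PrsModel(entries=df[cols].copy(), build=build)


# ---------------------------------------------------------------------------
# dosage and scoring
# ---------------------------------------------------------------------------

def dosage(
    gp: Sequence[float] | None = None,
    gt: str | None = None,
    effect_allele: str | None = None,
    alleles: tuple[str, str] | None = None,
    af_reference: float | None = None,
) -> float:
    """Expected effect-allele count in [0, 2].

    Fallback order: genotype probabilities (GP triple, hom-ref/het/hom-alt
    with the alternate as the effect allele), hard genotype call, then the
    Hardy-Weinberg expectation 2*AF from the reference panel of the
    participant's group.
    """
    if gp is not None:
        gp = np.asarray(gp, dtype=float)
        if gp.shape != (3,) or np.any(gp < 0) or abs(gp.sum() - 1.0) > 1e-6:
            raise ValueError("GP must be a probability triple summing to 1")
        return float(gp[1] + 2.0 * gp[2])
    if gt is not None:
        if effect_allele is None or alleles is None:
            # numeric GT with effect allele coded 1
            count = sum(1 for a in str(gt).replace("|", "/").split("/") if a == "1")
            return float(count)
        called = str(gt).replace("|", "/").split("/")
        idx_to_allele = {0: alleles[0], 1: alleles[1]}
        return float(
            sum(1 for a in called if idx_to_allele.get(int(a)) == effect_allele)
        )
    if af_reference is not None:
        if not 0.0 <= af_reference <= 1.0:
            raise ValueError("af_reference outside [0, 1]")
        return 2.0 * af_reference
    raise ValueError("dosage needs at least one of GP, GT, af_reference")


def score_participants(
    model: PrsModel, observations: pd.DataFrame,
    callability_max_missing: float | None = DEFAULT_CALLABILITY_MAX_MISSING,
) -> pd.Series:
    """Raw PRS per participant: sum of weight * dosage over model variants.

    Parameters
    ----------
    observations : DataFrame
        Columns: participant_id, variant_id, and any of gp0/gp1/gp2, GT,
        af_reference.  Observations for variants absent from the model are
        ignored with a warning; score variants with too many participants
        lacking both GP and GT are dropped (callability QC).
    """
    obs = observations.copy()
    known = set(model.entries["variant_id"])
    extra = set(obs["variant_id"]) - known
    if extra:
        log.warning("ignoring %d observed variants absent from the scoring model",
                    len(extra))
        obs = obs[obs["variant_id"].isin(known)]

    has_gp = obs.get("gp1")
    has_gp = has_gp.notna() if has_gp is not None else pd.Series(False, index=obs.index)
    gt_col = obs.get("GT")
    has_gt = gt_col.notna() & (gt_col.astype(str) != "") if gt_col is not None else \
        pd.Series(False, index=obs.index)

    if callability_max_missing is not None and len(obs):
        missing = (~(has_gp | has_gt)).groupby(obs["variant_id"]).mean()
        bad = set(missing[missing > callability_max_missing].index)
        if bad:
            log.info("dropping %d low-callability score variants", len(bad))
            keep = ~obs["variant_id"].isin(bad)
            obs, has_gp, has_gt = obs[keep], has_gp[keep], has_gt[keep]

    d = np.empty(len(obs))
    gp_idx = has_gp.to_numpy()
    if gp_idx.any():
        d[gp_idx] = (
            obs.loc[has_gp, "gp1"].to_numpy(float)
            + 2.0 * obs.loc[has_gp, "gp2"].to_numpy(float)
        )
    gt_idx = (~gp_idx) & has_gt.to_numpy()
    if gt_idx.any():
        d[gt_idx] = [
            dosage(gt=g) for g in obs.loc[gt_idx, "GT"].astype(str)
        ]
    af_idx = ~(gp_idx | gt_idx)
    if af_idx.any():
        if "af_reference" not in obs.columns:
            raise ValueError("observations lacking GP and GT need af_reference")
        d[af_idx] = 2.0 * obs.loc[af_idx, "af_reference"].to_numpy(float)

    weights = model.entries.set_index("variant_id")["effect_weight"]
    contrib = d * weights.reindex(obs["variant_id"]).to_numpy(float)
    return pd.Series(contrib).groupby(obs["participant_id"].to_numpy()).sum()


# ---------------------------------------------------------------------------
# group-wise percentiles, thresholds, AUC
# ---------------------------------------------------------------------------

def assign_percentiles(scores: pd.DataFrame) -> pd.DataFrame:
    """Within-group percentile ranks (average ranks for ties, 100*r/N).

    Parameters
    ----------
    scores : DataFrame with columns participant_id, genetic_group, raw_score.

    Returns the same frame with ``percentile`` added; empty groups are
    skipped with a warning, and groups are concatenated back so that each
    participant's percentile depends only on her own group.
    """
    out = []
    for group, sub in scores.groupby("genetic_group", sort=False):
        if sub.empty:
            log.warning("empty genetic-similarity group %s skipped", group)
            continue
        ranks = rankdata(sub["raw_score"].to_numpy(float), method="average")
        sub = sub.copy()
        sub["percentile"] = 100.0 * ranks / len(sub)
        out.append(sub)
    if not out:
        raise ValueError("no non-empty groups")
    return pd.concat(out).sort_index()


def standardize_within_group(
    scores: pd.DataFrame, reference_mask: pd.Series | None = None
) -> pd.Series:
    """Group-wise z-scores; moments taken over ``reference_mask`` rows
    (e.g. women without a breast-cancer diagnosis) when given."""
    z = pd.Series(np.nan, index=scores.index)
    for group, sub in scores.groupby("genetic_group", sort=False):
        ref = sub if reference_mask is None else sub[reference_mask.loc[sub.index]]
        mu = ref["raw_score"].mean()
        sd = ref["raw_score"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"degenerate score variance in group {group}")
        z.loc[sub.index] = (sub["raw_score"] - mu) / sd
    return z


def top_fraction_flags(percentiles, top_fraction: float) -> np.ndarray:
    """Boolean top-X% flags: percentile strictly above 100*(1 - X)."""
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    pct = np.asarray(percentiles, dtype=float)
    return pct > 100.0 * (1.0 - top_fraction)


def auc(scores, case_labels) -> float:
    """Rank-based AUC: P(case score > control score) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(case_labels, dtype=bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one case and one control")
    ranks = rankdata(s, method="average")
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
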