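"""Automated variant-interpretation cascade for population screening.

Pre-annotated small variants in the five breast-cancer genes (BRCA1, BRCA2,
PALB2, ATM, CHEK2) are labelled P/LP, B/LB, VUS or not_pathogenic by an
ordered rule cascade over ClinVar review status / clinical significance and
the LOFTEE high-confidence loss-of-function flag; variants failing gnomAD
site QC are excluded before the cascade.  Copy-number variants are handled
separately: only PASS deletions overlapping a protein-coding exon of the
MANE transcript count as pathogenic.

The cascade is deliberately simple and fully automated: for screening an
unselected population, most diagnostic-grade ACMG evidence types are
unavailable, and a reproducible rule set is preferred over manual review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import GENE_PRECEDENCE, GENES

log = logging.getLogger(__name__)

#: founder frameshift CHEK2 c.1100del, pathogenic regardless of ClinVar state
CHEK2_DEL1100C_RSID = "rs555607708"

#: cohort allele-frequency ceiling expected of a pathogenic variant
PLP_AF_CEILING = 0.001

P_LP = "P/LP"
B_LB = "B/LB"
VUS = "VUS"
NOT_PATHOGENIC = "not_pathogenic"
EXCLUDED = "excluded"

_EXPERT_PANEL = "reviewed by expert panel"
_MULTI_NO_CONFLICT = "criteria provided, multiple submitters, no conflicts"

_CLNSIG_MAP = {
    "pathogenic": P_LP,
    "likely pathogenic": P_LP,
    "pathogenic/likely pathogenic": P_LP,
    "benign": B_LB,
    "likely benign": B_LB,
    "benign/likely benign": B_LB,
    "uncertain significance": VUS,
}


def _norm(value: str | None) -> str:
    if value is None:
        return ""
    return str(value).strip().lower().replace("_", " ")


@dataclass
class AnnotatedVariant:
    """One pre-annotated variant record (small variant or CNV)."""

    variant_id: str
    gene: str
    consequence: str = ""
    rsid: str | None = None
    clnsig: str | None = None
    clnrevstat: str | None = None
    loftee: str = "none"  # HC | LC | none
    gnomad_filter_pass: bool = True
    af_gnomad: float = 0.0
    af_cohort: float = 0.0
    is_cnv: bool = False
    cnv_kind: str = "none"  # deletion | duplication | none
    cnv_pass: bool = True
    overlaps_coding_exon: bool = False
    manual_fail: bool = False

    def validate(self) -> None:
        if self.gene not in GENES:
            raise ValueError(
                f"{self.variant_id}: gene {self.gene!r} outside the 5-gene panel"
            )
        for name in ("af_gnomad", "af_cohort"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.variant_id}: {name} outside [0, 1]")
        if self.is_cnv != (self.cnv_kind != "none"):
            raise ValueError(
                f"{self.variant_id}: is_cnv inconsistent with cnv_kind"
            )


@dataclass(frozen=True)
class ClassificationLabel:
    label: str
    rule_fired: str


def classify_variant(v: AnnotatedVariant) -> ClassificationLabel:
    """Classify a small variant; first matching cascade branch wins.

    Order: site-QC exclusion, founder CHEK2 del1100C, expert-panel ClinVar,
    multi-submitter-no-conflict benign/uncertain, LOFTEE high-confidence
    loss of function, default not_pathogenic.
    """
    v.validate()
    if v.is_cnv:
        raise ValueError(f"{v.variant_id}: classify_variant expects a small variant")
    if not v.gnomad_filter_pass or v.manual_fail:
        return ClassificationLabel(EXCLUDED, "site_qc_fail")
    if v.rsid == CHEK2_DEL1100C_RSID:
        return ClassificationLabel(P_LP, "chek2_del1100c")
    revstat = _norm(v.clnrevstat)
    sig = _norm(v.clnsig)
    if revstat and revstat not in (_EXPERT_PANEL, _MULTI_NO_CONFLICT):
        log.debug("%s: unrecognized review status %r treated as absent",
                  v.variant_id, v.clnrevstat)
        revstat = ""
    if revstat == _EXPERT_PANEL:
        mapped = _CLNSIG_MAP.get(sig)
        if mapped is None:
            log.warning("%s: expert-panel significance %r not mapped; "
                        "treated as not pathogenic", v.variant_id, v.clnsig)
            return ClassificationLabel(NOT_PATHOGENIC, "expert_panel_other")
        return ClassificationLabel(mapped, "expert_panel")
    if revstat == _MULTI_NO_CONFLICT and _CLNSIG_MAP.get(sig) == B_LB:
        return ClassificationLabel(B_LB, "multi_submitter_benign")
    if revstat == _MULTI_NO_CONFLICT and _CLNSIG_MAP.get(sig) == VUS:
        return ClassificationLabel(VUS, "multi_submitter_vus")
    if v.loftee == "HC":
        return ClassificationLabel(P_LP, "loftee_hc")
    return ClassificationLabel(NOT_PATHOGENIC, "default")


def classify_cnv(v: AnnotatedVariant) -> ClassificationLabel:
    """Classify a copy-number variant: only PASS exonic deletions are P/LP."""
    v.validate()
    if not v.is_cnv:
        raise ValueError(f"{v.variant_id}: classify_cnv expects a CNV")
    if not v.cnv_pass or v.manual_fail:
        return ClassificationLabel(EXCLUDED, "cnv_qc_fail")
    if v.cnv_kind == "deletion" and v.overlaps_coding_exon:
        return ClassificationLabel(P_LP, "cnv_exonic_deletion")
    return ClassificationLabel(NOT_PATHOGENIC, "cnv_not_pathogenic")


def classify(v: AnnotatedVariant) -> ClassificationLabel:
    """Dispatch small variants and CNVs to the right cascade."""
    return classify_cnv(v) if v.is_cnv else classify_variant(v)


def classify_all(
    variants: Iterable[AnnotatedVariant],
) -> dict[str, ClassificationLabel]:
    return {v.variant_id: classify(v) for v in variants}


# ---------------------------------------------------------------------------
# carrier table
# ---------------------------------------------------------------------------

_HET_HOM = {"0/1", "1/0", "0|1", "1|0", "1/1", "1|1"}


def carrier_table(
    variants: Sequence[AnnotatedVariant],
    labels: Mapping[str, ClassificationLabel],
    genotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-participant carrier genes from genotypes over classified variants.

    A participant carries a gene iff she has at least one het/hom genotype
    for a P/LP variant in it.  Multi-gene carriers retain every gene; the
    single analysis group follows the fixed gene precedence
    BRCA1 > BRCA2 > PALB2 > ATM > CHEK2.

    Parameters
    ----------
    genotypes : DataFrame with columns participant_id, variant_id, GT.
    """
    by_id = {v.variant_id: v for v in variants}
    missing = set(genotypes["variant_id"]) - set(by_id)
    if missing:
        raise ValueError(f"genotypes reference unknown variants: {sorted(missing)[:5]}")
    plp = {
        vid for vid, lab in labels.items()
        if lab.label == P_LP and vid in by_id
    }
    carriers: dict[str, set[str]] = {}
    for row in genotypes.itertuples(index=False):
        if row.variant_id in plp and str(row.GT) in _HET_HOM:
            carriers.setdefault(row.participant_id, set()).add(by_id[row.variant_id].gene)
    records = []
    for pid in pd.unique(genotypes["participant_id"]):
        genes = sorted(carriers.get(pid, set()), key=GENE_PRECEDENCE.__getitem__)
        records.append(
            {
                "participant_id": pid,
                "carrier_genes": ",".join(genes),
                "analysis_group": genes[0] if genes else "",
            }
        )
    return pd.DataFrame(records)


def analysis_gene(carrier_genes: Iterable[str]) -> str | None:
    """Single analysis-group gene for a (possibly multi-gene) carrier."""
    genes = [g for g in carrier_genes if g in GENE_PRECEDENCE]
    if not genes:
        return None
    return min(genes, key=GENE_PRECEDENCE.__getitem__)


def af_sanity_report(
    variants: Sequence[AnnotatedVariant],
    labels: Mapping[str, ClassificationLabel],
) -> pd.DataFrame:
    """Flag P/LP variants with cohort AF >= 0.1% for review.

    The founder CHEK2 del1100C is the known common exception and is never
    flagged.  This is a report only; no label is changed.
    """
    rows = []
    for v in variants:
        lab = labels.get(v.variant_id)
        if lab is None or lab.label != P_LP:
            continue
        if v.rsid == CHEK2_DEL1100C_RSID:
            continue
        if v.af_cohort >= PLP_AF_CEILING:
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "gene": v.gene,
                    "af_cohort": v.af_cohort,
                    "note": f"P/LP with cohort AF >= {PLP_AF_CEILING:.3%}",
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "gene", "af_cohort", "note"])


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

_BOOL_COLS = ("gnomad_filter_pass", "is_cnv", "cnv_pass", "overlaps_coding_exon",
              "manual_fail")


def read_variants(path: str | Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for rec in df.to_dict("records"):
        kwargs: dict = {
            "variant_id": rec["variant_id"],
            "gene": rec["gene"],
            "consequence": rec.get("consequence", ""),
            "rsid": rec.get("rsid") or None,
            "clnsig": rec.get("clnsig") or None,
            "clnrevstat": rec.get("clnrevstat") or None,
            "loftee": rec.get("loftee", "none") or "none",
            "af_gnomad": float(rec.get("af_gnomad") or 0.0),
            "af_cohort": float(rec.get("af_cohort") or 0.0),
            "cnv_kind": rec.get("cnv_kind", "none") or "none",
        }
        for col, default in zip(_BOOL_COLS, ("true", "false", "true", "false", "false")):
            raw = str(rec.get(col, default) or default).strip().lower()
            kwargs[col] = raw in ("true", "1", "yes")
        v = AnnotatedVariant(**kwargs)
        v.validate()
        out.append(v)
    return out


def write_labels(
    variants: Sequence[AnnotatedVariant],
    labels: Mapping[str, ClassificationLabel],
    path: str | Path,
) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "label": labels[v.variant_id].label,
            "rule_fired": labels[v.variant_id].rule_fired,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
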