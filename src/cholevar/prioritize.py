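"""Inclusion filtering and the seven-predictor in-silico consensus.

A non-synonymous or LoF variant passes the MAF < 5% gate (gnomAD AF when
recorded, else cohort AF) and is included when at least one of four criteria
fires: (1) an EHR phenotype is attached; (2) the variant is known in the
literature; (3) it is cohort-private (no recorded gnomAD frequency but a
cohort frequency); (4) all seven in-silico predictors concordantly call it
deleterious. Variants above the MAF gate are retained only via the phenotype
criterion and flagged ``maf_exempt`` — phenotype-linked common variants are
deliberately kept in view.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

from cholevar.core import PREDICTOR_TOOLS, PredictorPanel, VariantRecord
from cholevar.consequence import ConsequenceClass, classify, is_lof

__all__ = [
    "PredictorThresholds",
    "InclusionDecision",
    "predictor_call",
    "unanimous_insilico",
    "passes_inclusion",
    "filter_table",
]


@dataclass(frozen=True)
class PredictorThresholds:
    """Per-tool deleteriousness cutoffs (each tool's published recommendation).

    SIFT is damaging at or below its cutoff; the other numeric tools at or
    above; MetaLR/MetaSVM accept the categorical "D" call or a score >= 0.5.
    """

    sift_max: float = 0.05
    polyphen_min: float = 0.446
    cadd_min: float = 20.0
    revel_min: float = 0.5
    mcap_min: float = 0.025
    meta_score_min: float = 0.5


def predictor_call(
    tool: str,
    value: float | str | None,
    thresholds: PredictorThresholds = PredictorThresholds(),
) -> Literal["deleterious", "tolerated", "unknown"]:
    """Call one predictor slot as deleterious/tolerated/unknown."""
    if tool not in PREDICTOR_TOOLS:
        raise ValueError(f"unknown predictor tool {tool!r}; expected one of "
                         f"{', '.join(PREDICTOR_TOOLS)}")
    if value is None:
        return "unknown"
    if tool in ("metalr", "metasvm"):
        if isinstance(value, str):
            return "deleterious" if value.upper() == "D" else "tolerated"
        return (
            "deleterious" if value >= thresholds.meta_score_min else "tolerated"
        )
    value = float(value)
    if tool == "sift":
        return "deleterious" if value <= thresholds.sift_max else "tolerated"
    cutoff = {
        "polyphen": thresholds.polyphen_min,
        "cadd": thresholds.cadd_min,
        "revel": thresholds.revel_min,
        "mcap": thresholds.mcap_min,
    }[tool]
    return "deleterious" if value >= cutoff else "tolerated"


def unanimous_insilico(
    panel: PredictorPanel,
    thresholds: PredictorThresholds = PredictorThresholds(),
) -> bool:
    """True iff all seven tools are present and all seven call deleterious."""
    return all(
        predictor_call(t, panel.get(t), thresholds) == "deleterious"
        for t in PREDICTOR_TOOLS
    )


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    reasons: frozenset[str] = frozenset()
    maf_pass: bool = True
    maf_exempt: bool = False


def passes_inclusion(
    record: VariantRecord,
    thresholds: PredictorThresholds = PredictorThresholds(),
    maf_cutoff: float = 0.05,
    maf_exemption: bool = True,
) -> InclusionDecision:
    """Apply the MAF gate plus the 4-way OR inclusion criteria to one record."""
    cls = record.consequence_class or classify(record)
    if not (cls is ConsequenceClass.MISSENSE or is_lof(cls)):
        return InclusionDecision(False, frozenset(), True)

    af = record.af_gnomad if record.af_gnomad is not None else record.af_cohort
    maf_pass = af is None or af < maf_cutoff

    reasons = set()
    if record.has_phenotype:
        reasons.add("has_phenotype")
    if record.literature_known:
        reasons.add("literature_known")
    if record.af_gnomad is None and record.af_cohort is not None:
        reasons.add("cohort_private")
    if unanimous_insilico(record.predictor_panel, thresholds):
        reasons.add("unanimous_insilico")

    if not reasons:
        return InclusionDecision(False, frozenset(), maf_pass)
    if maf_pass:
        return InclusionDecision(True, frozenset(reasons), True)
    if maf_exemption and "has_phenotype" in reasons:
        return InclusionDecision(True, frozenset(reasons), False, maf_exempt=True)
    return InclusionDecision(False, frozenset(reasons), False)


@dataclass
class FilterResult:
    included: list[VariantRecord]
    decisions: dict[str, InclusionDecision]
    per_gene_counts: dict[str, int] = field(default_factory=dict)


def filter_table(
    records: Iterable[VariantRecord],
    thresholds: PredictorThresholds = PredictorThresholds(),
    maf_cutoff: float = 0.05,
    maf_exemption: bool = True,
) -> FilterResult:
    """Filter a record list; preserves input order and counts per gene."""
    records = list(records)
    decisions = {
        r.variant_id: passes_inclusion(r, thresholds, maf_cutoff, maf_exemption)
        for r in records
    }
    included = [r for r in records if decisions[r.variant_id].included]
    counts = Counter(r.gene for r in included)
    return FilterResult(included, decisions, dict(counts))
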