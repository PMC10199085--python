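"""Bidirectional phenotype <-> genotype linkage.

Phenotype-to-genotype: select ICP cases from EHR-style records, either by the
ICD-10 obstetric-cholestasis diagnosis code (O26.6 by default) or by a total
serum bile-acid threshold (>= 10 umol/L; >= 40 umol/L flags severe disease),
and report discordances between the two routes (code-positive volunteers with
no bile-acid measurements, and raised-bile-acid volunteers without the code).
Genotype-to-phenotype: tally variants per gene by their attached EHR phenotype
groups and emit per-volunteer case reports of carried variants.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from cholevar.core import (
    GenotypeMatrix,
    IcpCaseReportRow,
    PhenotypeRecord,
    VariantRecord,
)
from cholevar.consequence import classify, is_lof

__all__ = [
    "LinkageCriteria",
    "LinkageReport",
    "select_icp_cases",
    "flag_severe",
    "genotype_phenotype_counts",
    "icp_case_report",
]


@dataclass(frozen=True)
class LinkageCriteria:
    tsba_threshold: float = 10.0     # umol/L, inclusive
    severe_threshold: float = 40.0   # umol/L, inclusive
    icd10_code: str = "O26.6"
    require_clinician_verification: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.tsba_threshold < self.severe_threshold:
            raise ValueError(
                "need 0 < tsba_threshold < severe_threshold "
                f"(got {self.tsba_threshold}, {self.severe_threshold})"
            )


@dataclass
class LinkageReport:
    strategy: str
    selected: list[str]
    highest_tsba: dict[str, float | None]
    code_positive_ba_missing: list[str] = field(default_factory=list)
    ba_positive_code_negative: list[str] = field(default_factory=list)


def _by_code(rec: PhenotypeRecord, criteria: LinkageCriteria) -> bool:
    if criteria.icd10_code not in rec.icd10_codes:
        return False
    return rec.icp_verified or not criteria.require_clinician_verification


def _by_ba(rec: PhenotypeRecord, criteria: LinkageCriteria) -> bool:
    top = rec.highest_tsba
    return top is not None and top >= criteria.tsba_threshold


def select_icp_cases(
    records: Iterable[PhenotypeRecord],
    criteria: LinkageCriteria = LinkageCriteria(),
    strategy: Literal["by_code", "by_ba", "union"] = "by_code",
) -> LinkageReport:
    """Select ICP cases by diagnosis code, bile-acid threshold, or their union."""
    if strategy not in ("by_code", "by_ba", "union"):
        raise ValueError(f"unknown strategy {strategy!r}")
    records = list(records)
    selected = []
    highest: dict[str, float | None] = {}
    code_no_ba = []
    ba_no_code = []
    for rec in records:
        code_hit = _by_code(rec, criteria)
        ba_hit = _by_ba(rec, criteria)
        take = {
            "by_code": code_hit,
            "by_ba": ba_hit,
            "union": code_hit or ba_hit,
        }[strategy]
        if take:
            selected.append(rec.sample_id)
            highest[rec.sample_id] = rec.highest_tsba
        if code_hit and rec.highest_tsba is None:
            code_no_ba.append(rec.sample_id)
        if ba_hit and not code_hit:
            ba_no_code.append(rec.sample_id)
    return LinkageReport(strategy, selected, highest, code_no_ba, ba_no_code)


def flag_severe(
    record: PhenotypeRecord | IcpCaseReportRow,
    criteria: LinkageCriteria = LinkageCriteria(),
) -> bool | None:
    """Severe-disease flag: peak TSBA at or above the severe threshold.

    Returns ``None`` (unknown), not False, when no measurement exists.
    """
    top = record.highest_tsba
    if top is None:
        return None
    return top >= criteria.severe_threshold


def genotype_phenotype_counts(
    records: Iterable[VariantRecord],
) -> dict[str, Counter]:
    """Per-gene variant counts by phenotype group.

    A variant attached to multiple groups counts once per group.
    """
    out: dict[str, Counter] = {}
    for rec in records:
        tally = out.setdefault(rec.gene, Counter())
        for group in rec.phenotype_groups:
            tally[group] += 1
    return out


def icp_case_report(
    selected: Sequence[str],
    matrix: GenotypeMatrix,
    records: Iterable[VariantRecord],
    phenotypes: Iterable[PhenotypeRecord],
) -> tuple[list[IcpCaseReportRow], list[str]]:
    """Per-volunteer report of carried variants among selected samples.

    Returns (rows, no_variant_annex): one row per selected sample carrying at
    least one listed variant; carriers of nothing are returned separately.
    Raises ``KeyError`` naming any selected id absent from the matrix.
    """
    by_id = {r.variant_id: r for r in records}
    pheno_by_id = {p.sample_id: p for p in phenotypes}
    sample_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows: list[IcpCaseReportRow] = []
    annex: list[str] = []
    for sid in selected:
        if sid not in sample_index:
            raise KeyError(f"selected sample {sid!r} absent from genotype matrix")
        i = sample_index[sid]
        carried = []
        for j, key in enumerate(matrix.variant_keys):
            count = int(matrix.counts[i, j])
            if count < 1 or key not in by_id:
                continue
            rec = by_id[key]
            cls = rec.consequence_class or classify(rec)
            kind = "LoF" if is_lof(cls) else "Non-synonymous"
            zyg = "hom" if count == 2 else "het"
            carried.append((rec.gene, rec.protein_change or rec.cdna_change, zyg, kind))
        if not carried:
            annex.append(sid)
            continue
        pheno = pheno_by_id.get(sid)
        rows.append(
            IcpCaseReportRow(sid, pheno.highest_tsba if pheno else None, carried)
        )
    return rows, annex
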