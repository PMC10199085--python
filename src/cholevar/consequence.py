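"""Consequence classification: non-synonymous vs loss-of-function subclasses.

Classification prefers an explicit consequence label when the annotation
carries one, then falls back to parsing the HGVS protein notation embedded in
the transcript/protein-change strings. The LoF set is {frameshift,
stop_gained, splice_acceptor, start_lost_frameshift}; composite
frameshift+start-lost and frameshift+splice-region labels count as frameshift
in tallies.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from cholevar.core import VariantRecord

__all__ = ["ConsequenceClass", "LofTally", "classify", "is_lof", "tally_lof",
           "classify_all"]


class ConsequenceClass(str, Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAINED = "stop_gained"
    SPLICE_ACCEPTOR = "splice_acceptor"
    START_LOST_FRAMESHIFT = "start_lost_frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


LOF_CLASSES = frozenset(
    {
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.STOP_GAINED,
        ConsequenceClass.SPLICE_ACCEPTOR,
        ConsequenceClass.START_LOST_FRAMESHIFT,
    }
)

_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp"
    "|Tyr|Val|Ter|Sec"
)
# p.Arg595Ter / p.Gly1254Ser style
_HGVS3 = re.compile(rf"p\.\(?({_AA3})(\d+)({_AA3})", re.IGNORECASE)
# G1254S / R595* / W239x short style
_SHORT = re.compile(r"^([A-Z])(\d+)([A-Z*xX])$")
# c. splice-acceptor positions: -1 or -2 relative to exon start, e.g. c.2611-2A>T
_SPLICE_ACC = re.compile(r"c\.[\d_]+-(1|2)(?:_|[ACGT>])", re.IGNORECASE)


def _from_label(label: str) -> ConsequenceClass | None:
    s = label.strip().lower().replace("-", "_").replace(" ", "")
    if not s:
        return None
    has_fs = "frameshift" in s
    if has_fs and "start_lost" in s:
        return ConsequenceClass.START_LOST_FRAMESHIFT
    if "splice_acceptor" in s:
        return ConsequenceClass.SPLICE_ACCEPTOR
    if has_fs:
        return ConsequenceClass.FRAMESHIFT
    if "stop_gained" in s or "stopgain" in s or "nonsense" in s:
        return ConsequenceClass.STOP_GAINED
    if "non_synonymous" in s or "nonsynonymous" in s or "missense" in s:
        return ConsequenceClass.MISSENSE
    if "synonymous" in s:
        return ConsequenceClass.SYNONYMOUS
    return None


def _from_hgvs_p(text: str) -> ConsequenceClass | None:
    if not text:
        return None
    if re.search(r"fs(Ter\d*)?", text) and "p." in text:
        return ConsequenceClass.FRAMESHIFT
    m = _HGVS3.search(text)
    if m:
        ref, alt = m.group(1).capitalize(), m.group(3).capitalize()
        if alt == "Ter":
            return ConsequenceClass.STOP_GAINED
        return (
            ConsequenceClass.SYNONYMOUS if ref == alt else ConsequenceClass.MISSENSE
        )
    return None


def _from_short(text: str) -> ConsequenceClass | None:
    m = _SHORT.match(text.strip())
    if not m:
        return None
    ref, alt = m.group(1), m.group(3)
    if alt in ("*", "x", "X"):
        return ConsequenceClass.STOP_GAINED
    return ConsequenceClass.SYNONYMOUS if ref == alt else ConsequenceClass.MISSENSE


def classify(record: VariantRecord) -> ConsequenceClass:
    """Deterministically classify one variant record.

    Order of evidence: explicit consequence label, HGVS-p in the transcript
    string, cDNA splice-acceptor pattern, then the short protein label.
    Unparseable rows classify as OTHER with a warning, never a silent drop.
    """
    for route in (
        _from_label(record.consequence_label),
        _from_hgvs_p(record.transcript_id),
        _from_hgvs_p(record.protein_change),
        (
            ConsequenceClass.SPLICE_ACCEPTOR
            if _SPLICE_ACC.search(record.cdna_change or "")
            or _SPLICE_ACC.search(record.transcript_id or "")
            else None
        ),
        _from_short(record.protein_change),
    ):
        if route is not None:
            return route
    warnings.warn(
        f"{record.variant_id}: unparseable consequence "
        f"(label={record.consequence_label!r}, "
        f"protein_change={record.protein_change!r}); classified as 'other'",
        stacklevel=2,
    )
    return ConsequenceClass.OTHER


def is_lof(cls: ConsequenceClass) -> bool:
    """True iff the class belongs to the loss-of-function set."""
    return cls in LOF_CLASSES


@dataclass(frozen=True)
class LofTally:
    """LoF counts; frameshift includes start-lost/frameshift composites."""

    frameshift: int
    stop_gained: int
    splice_acceptor: int

    @property
    def total(self) -> int:
        return self.frameshift + self.stop_gained + self.splice_acceptor


def classify_all(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Annotate each record's ``consequence_class`` in place; returns records."""
    out = list(records)
    for rec in out:
        rec.consequence_class = classify(rec)
    return out


def tally_lof(records: Iterable[VariantRecord]) -> LofTally:
    """Tally LoF subclasses over records (classifying on the fly if needed)."""
    fs = sg = sa = 0
    for rec in records:
        cls = rec.consequence_class or classify(rec)
        if cls in (ConsequenceClass.FRAMESHIFT, ConsequenceClass.START_LOST_FRAMESHIFT):
            fs += 1
        elif cls is ConsequenceClass.STOP_GAINED:
            sg += 1
        elif cls is ConsequenceClass.SPLICE_ACCEPTOR:
            sa += 1
    return LofTally(fs, sg, sa)
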