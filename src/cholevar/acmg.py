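"""ACMG-AMP evidence-combining engine.

Maps a set of evidence codes (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7)
to the five-tier verdict via the guideline's combining clauses:

Pathogenic
    PVS1 + (>=1 PS | >=2 PM | 1 PM + 1 PP | >=2 PP); or >=2 PS; or
    1 PS + (>=3 PM | 2 PM + >=2 PP | 1 PM + >=4 PP)
Likely pathogenic
    PVS1 + 1 PM; 1 PS + 1-2 PM; 1 PS + >=2 PP; >=3 PM; 2 PM + >=2 PP;
    1 PM + >=4 PP
Benign
    BA1 alone (stand-alone, overrides everything); or >=2 BS
Likely benign
    1 BS + 1 BP; or >=2 BP
otherwise VUS.

Two conflict conventions are provided. ``strict`` follows the guideline
literally: when a pathogenic-tier and a benign-tier rule both fire the verdict
is VUS with ``conflict_flag`` set (BA1 excepted — it stands alone as Benign).
``paper_tolerant`` reproduces the benign-leaning calls seen in published
candidate-gene tables: the benign side wins a conflict, and a Benign verdict
is downgraded to Likely benign when moderate-or-stronger pathogenic codes
co-occur. PP5/BP6 (reputable-source) are accepted as ordinary supporting
codes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "VALID_CODES",
    "TIERS",
    "Verdict",
    "ConcordanceReport",
    "parse_codes",
    "combine",
    "validate_against_printed",
]

VALID_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

TIERS = ("Benign", "Likely benign", "VUS", "Likely pathogenic", "Pathogenic")

_ALIAS = {
    "P": "Pathogenic",
    "LP": "Likely pathogenic",
    "VUS": "VUS",
    "LB": "Likely benign",
    "B": "Benign",
    "LIKELY PATHOGENIC": "Likely pathogenic",
    "LIKELY BENIGN": "Likely benign",
    "PATHOGENIC": "Pathogenic",
    "BENIGN": "Benign",
}


def normalize_tier(label: str) -> str:
    """Map a printed verdict label ('LP', 'Benign', ...) to its canonical tier."""
    key = label.strip().upper()
    if key not in _ALIAS:
        raise ValueError(f"unrecognized verdict label {label!r}")
    return _ALIAS[key]


@dataclass(frozen=True)
class Verdict:
    tier: str  # one of TIERS
    conflict_flag: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.tier + (" (conflicting evidence)" if self.conflict_flag else "")


def parse_codes(text: str | Iterable[str] | None) -> frozenset[str]:
    """Parse a comma-separated evidence-code string; whitespace-tolerant."""
    if text is None:
        return frozenset()
    if not isinstance(text, str):
        tokens = [str(t).strip() for t in text]
    else:
        tokens = [t.strip() for t in re.split(r"[,;]", text)]
    codes = set()
    for tok in tokens:
        if not tok:
            continue
        code = tok.upper()
        if code not in VALID_CODES:
            raise ValueError(f"unknown ACMG-AMP evidence code {tok!r}")
        codes.add(code)
    return frozenset(codes)


def _strength_counts(codes: frozenset[str]):
    pvs = sum(c == "PVS1" for c in codes)
    ps = sum(c.startswith("PS") for c in codes)
    pm = sum(c.startswith("PM") for c in codes)
    pp = sum(c.startswith("PP") for c in codes)
    ba = sum(c == "BA1" for c in codes)
    bs = sum(c.startswith("BS") for c in codes)
    bp = sum(c.startswith("BP") for c in codes)
    return pvs, ps, pm, pp, ba, bs, bp


def _pathogenic_tier(pvs: int, ps: int, pm: int, pp: int) -> str | None:
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2):
        return "Pathogenic"
    if ps >= 2:
        return "Pathogenic"
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return "Pathogenic"
    if pvs >= 1 and pm == 1:
        return "Likely pathogenic"
    if ps == 1 and 1 <= pm <= 2:
        return "Likely pathogenic"
    if ps == 1 and pp >= 2:
        return "Likely pathogenic"
    if pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4):
        return "Likely pathogenic"
    return None


def _benign_tier(ba: int, bs: int, bp: int) -> str | None:
    if ba >= 1 or bs >= 2:
        return "Benign"
    if (bs == 1 and bp >= 1) or bp >= 2:
        return "Likely benign"
    return None


def combine(evidence: frozenset[str] | Iterable[str] | str, mode: str = "strict") -> Verdict:
    """Combine an evidence-code set into a five-tier verdict."""
    if mode not in ("strict", "paper_tolerant"):
        raise ValueError(f"unknown mode {mode!r}")
    codes = parse_codes(evidence) if isinstance(evidence, str) else frozenset(evidence)
    bad = codes - VALID_CODES
    if bad:
        raise ValueError(f"unknown ACMG-AMP evidence code(s) {sorted(bad)}")
    pvs, ps, pm, pp, ba, bs, bp = _strength_counts(codes)
    path = _pathogenic_tier(pvs, ps, pm, pp)
    ben = _benign_tier(ba, bs, bp)
    both_fire = path is not None and ben is not None

    if ba >= 1:  # stand-alone benign overrides either way
        return Verdict("Benign", conflict_flag=both_fire)
    if mode == "strict":
        if both_fire:
            return Verdict("VUS", conflict_flag=True)
        return Verdict(path or ben or "VUS")
    # paper_tolerant: benign side wins; Benign downgraded under moderate+
    # pathogenic co-evidence
    if ben is not None:
        tier = ben
        if tier == "Benign" and (pvs + ps + pm) >= 1:
            tier = "Likely benign"
        return Verdict(tier, conflict_flag=both_fire)
    return Verdict(path or "VUS")


@dataclass
class ConcordanceReport:
    n_match: int
    n_mismatch: int
    mismatches: list[tuple[str, str, str]]  # (variant_id, engine, printed)

    @property
    def n_total(self) -> int:
        return self.n_match + self.n_mismatch


def validate_against_printed(records, mode: str = "strict") -> ConcordanceReport:
    """Compare engine verdicts with the printed verdict column, row by row.

    Rows without a printed verdict are skipped; every discordant row is listed
    with both verdicts.
    """
    n_match = 0
    mismatches = []
    for rec in records:
        if not rec.printed_verdict:
            continue
        engine = combine(rec.acmg_codes, mode=mode).tier
        printed = normalize_tier(rec.printed_verdict)
        if engine == printed:
            n_match += 1
        else:
            mismatches.append((rec.variant_id, engine, printed))
    return ConcordanceReport(n_match, len(mismatches), mismatches)
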