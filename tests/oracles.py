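"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by literal enumeration — exact rational
hypergeometric sums for the two-sided Fisher test, and a flat clause list for
the ACMG-AMP combining rules — and share no code with the package paths they
check.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (min-likelihood).

    Sums the point probabilities of every table sharing the observed margins
    whose probability is <= that of the observed table (relative tolerance
    1e-7, matching standard implementations), in exact rational arithmetic.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0:
        return 1.0
    denom = comb(n, col1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = {
        x: Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)
        for x in range(lo, hi + 1)
    }
    cutoff = probs[a] * (Fraction(10**7 + 1, 10**7))
    p = sum(pr for pr in probs.values() if pr <= cutoff)
    return float(min(p, Fraction(1)))


# --- ACMG-AMP combining clauses, enumerated literally ----------------------

_PATHOGENIC_CLAUSES = (
    lambda vs, s, m, p: vs >= 1 and s >= 1,
    lambda vs, s, m, p: vs >= 1 and m >= 2,
    lambda vs, s, m, p: vs >= 1 and m == 1 and p == 1,
    lambda vs, s, m, p: vs >= 1 and m == 1 and p >= 1,  # 1 PM + 1 PP (>=)
    lambda vs, s, m, p: vs >= 1 and p >= 2,
    lambda vs, s, m, p: s >= 2,
    lambda vs, s, m, p: s == 1 and m >= 3,
    lambda vs, s, m, p: s == 1 and m == 2 and p >= 2,
    lambda vs, s, m, p: s == 1 and m == 1 and p >= 4,
)

_LIKELY_PATHOGENIC_CLAUSES = (
    lambda vs, s, m, p: vs >= 1 and m == 1,
    lambda vs, s, m, p: s == 1 and m in (1, 2),
    lambda vs, s, m, p: s == 1 and p >= 2,
    lambda vs, s, m, p: m >= 3,
    lambda vs, s, m, p: m == 2 and p >= 2,
    lambda vs, s, m, p: m == 1 and p >= 4,
)

_BENIGN_CLAUSES = (
    lambda ba, bs, bp: ba >= 1,
    lambda ba, bs, bp: bs >= 2,
)

_LIKELY_BENIGN_CLAUSES = (
    lambda ba, bs, bp: bs == 1 and bp >= 1,
    lambda ba, bs, bp: bp >= 2,
)


def acmg_oracle(codes: frozenset[str], mode: str = "strict") -> tuple[str, bool]:
    """(tier, conflict_flag) by enumerating the combining clauses one by one."""
    vs = sum(1 for c in codes if c.startswith("PVS"))
    s = sum(1 for c in codes if c.startswith("PS"))
    m = sum(1 for c in codes if c.startswith("PM"))
    p = sum(1 for c in codes if c.startswith("PP"))
    ba = sum(1 for c in codes if c.startswith("BA"))
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))

    path_tier = None
    if any(cl(vs, s, m, p) for cl in _PATHOGENIC_CLAUSES):
        path_tier = "Pathogenic"
    elif any(cl(vs, s, m, p) for cl in _LIKELY_PATHOGENIC_CLAUSES):
        path_tier = "Likely pathogenic"
    benign_tier = None
    if any(cl(ba, bs, bp) for cl in _BENIGN_CLAUSES):
        benign_tier = "Benign"
    elif any(cl(ba, bs, bp) for cl in _LIKELY_BENIGN_CLAUSES):
        benign_tier = "Likely benign"
    both = path_tier is not None and benign_tier is not None

    if ba >= 1:
        return "Benign", both
    if mode == "strict":
        if both:
            return "VUS", True
        return path_tier or benign_tier or "VUS", False
    if benign_tier is not None:
        tier = benign_tier
        if tier == "Benign" and (vs + s + m) >= 1:
            tier = "Likely benign"
        return tier, both
    return path_tier or "VUS", False
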