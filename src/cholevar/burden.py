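"""Collapsed-carrier (CMC-style) exact burden testing.

Per gene, samples are collapsed to a single carrier indicator over qualifying
rare variants (cohort allele frequency <= 0.01 by default) and the resulting
carrier/non-carrier x case/control 2x2 table is tested with Fisher's exact
test. The two-sided p-value follows the minimum-likelihood convention: the sum
over all tables with the observed margins whose point hypergeometric
probability does not exceed that of the observed table.

Also provided: a cohort-vs-cohort comparison of rare-variant proportions, and
co-carrier grouping — variants carried by exactly the same samples — as an
exact-carrier-set proxy for linkage-disequilibrium observations (no r^2 is
estimated).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from cholevar.core import GenotypeMatrix

__all__ = [
    "BurdenConfig",
    "BurdenResult",
    "CohortComparison",
    "EmptyCollapseError",
    "collapse",
    "fisher_exact_2x2",
    "cmc_exact",
    "cohort_variant_comparison",
    "co_carrier_groups",
]


class EmptyCollapseError(ValueError):
    """A gene has no qualifying variant (or no carrier): no p-value is defined."""


@dataclass(frozen=True)
class BurdenConfig:
    af_threshold: float = 0.01
    alpha: float = 0.05
    af_source: Literal["cohort", "annotation"] = "cohort"
    alternative: Literal["two-sided", "greater"] = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 < self.af_threshold < 1.0:
            raise ValueError(f"af_threshold {self.af_threshold} outside (0, 1)")


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: carrier/non; cols: case/ctrl
    p_value: float
    n_variants_collapsed: int


@dataclass(frozen=True)
class CohortComparison:
    label: str
    k1: int
    n1: int
    k2: int
    n2: int
    p_value: float


def _gene_columns(matrix: GenotypeMatrix, gene: str) -> list[int]:
    prefix = f"{gene}:"
    return [j for j, k in enumerate(matrix.variant_keys) if k.startswith(prefix)]


def _qualifying_columns(
    matrix: GenotypeMatrix,
    gene: str,
    config: BurdenConfig,
    annotation_af: dict[str, float] | None,
) -> list[int]:
    cols = _gene_columns(matrix, gene)
    if config.af_source == "annotation":
        if annotation_af is None:
            raise ValueError("af_source='annotation' requires annotation_af")
        afs = np.array(
            [annotation_af.get(matrix.variant_keys[j], np.nan) for j in cols]
        )
    else:
        afs = matrix.alt_allele_frequency()[cols]
    return [
        j
        for j, af in zip(cols, afs)
        if np.isfinite(af) and af <= config.af_threshold
    ]


def collapse(
    matrix: GenotypeMatrix,
    gene: str,
    config: BurdenConfig = BurdenConfig(),
    annotation_af: dict[str, float] | None = None,
) -> np.ndarray:
    """Boolean carrier vector: >=1 alternate allele at >=1 qualifying variant.

    A variant qualifies iff its allele frequency is <= ``config.af_threshold``;
    the AF comes from the analyzed cohort's genotypes (default) or, with
    ``af_source='annotation'``, from ``annotation_af`` keyed by variant id.
    Raises :class:`EmptyCollapseError` when no variant qualifies.
    """
    qualifying = _qualifying_columns(matrix, gene, config, annotation_af)
    if not qualifying:
        raise EmptyCollapseError(
            f"{gene}: no variant with AF <= {config.af_threshold}"
        )
    return (matrix.counts[:, qualifying] >= 1).any(axis=1)


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> float:
    """Fisher's exact p for the table [[a, b], [c, d]].

    Two-sided by minimum-likelihood summation over the hypergeometric support;
    degenerate tables (an all-zero margin) give p = 1 by convention.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(min(p, 1.0))


def cmc_exact(
    matrix: GenotypeMatrix,
    gene: str,
    case_labels: Sequence[bool] | np.ndarray,
    config: BurdenConfig = BurdenConfig(),
    annotation_af: dict[str, float] | None = None,
) -> BurdenResult:
    """Collapsed-carrier exact test for one gene.

    ``case_labels`` aligns with ``matrix.sample_ids``; both groups must be
    non-empty.
    """
    cases = np.asarray(case_labels, dtype=bool)
    if cases.shape != (matrix.n_samples,):
        raise ValueError(
            f"case_labels length {cases.size} != {matrix.n_samples} samples"
        )
    if cases.all() or not cases.any():
        raise ValueError("both case and control groups must be non-empty")
    qualifying = _qualifying_columns(matrix, gene, config, annotation_af)
    if not qualifying:
        raise EmptyCollapseError(
            f"{gene}: no variant with AF <= {config.af_threshold}"
        )
    carrier = (matrix.counts[:, qualifying] >= 1).any(axis=1)
    if not carrier.any():
        raise EmptyCollapseError(f"{gene}: zero carriers after collapsing")
    a = int((carrier & cases).sum())       # carrier cases
    b = int((carrier & ~cases).sum())      # carrier controls
    c = int((~carrier & cases).sum())
    d = int((~carrier & ~cases).sum())
    p = fisher_exact_2x2(a, b, c, d, alternative=config.alternative)
    n_collapsed = len(qualifying)
    return BurdenResult(gene, ((a, b), (c, d)), p, n_collapsed)


def cohort_variant_comparison(
    k1: int, n1: int, k2: int, n2: int, label: str = ""
) -> CohortComparison:
    """Compare variant proportions k1/n1 vs k2/n2 between two cohorts."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both cohorts")
    p = fisher_exact_2x2(k1, n1 - k1, k2, n2 - k2)
    return CohortComparison(label, k1, n1, k2, n2, p)


def co_carrier_groups(matrix: GenotypeMatrix) -> list[list[str]]:
    """Maximal groups (size >= 2) of variants with identical non-empty carrier sets.

    Ordering is deterministic: groups sorted by their first variant key in
    matrix order, members in matrix order.
    """
    by_carriers: dict[frozenset[int], list[str]] = {}
    for j, key in enumerate(matrix.variant_keys):
        carriers = frozenset(np.flatnonzero(matrix.counts[:, j] >= 1).tolist())
        if carriers:
            by_carriers.setdefault(carriers, []).append(key)
    order = {k: i for i, k in enumerate(matrix.variant_keys)}
    groups = [sorted(g, key=order.__getitem__) for g in by_carriers.values() if len(g) >= 2]
    return sorted(groups, key=lambda g: order[g[0]])
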