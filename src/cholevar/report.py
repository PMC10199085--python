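"""Per-gene summary matrix: variants, inclusion, verdict and phenotype tallies."""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

from cholevar import acmg
from cholevar.core import VariantRecord, gene_registry
from cholevar.phenolink import genotype_phenotype_counts

__all__ = ["render_summary", "summary_to_markdown"]

_VERDICT_COLS = {
    "Pathogenic": "n_pathogenic",
    "Likely pathogenic": "n_likely_pathogenic",
    "VUS": "n_vus",
    "Likely benign": "n_likely_benign",
    "Benign": "n_benign",
}
_PHENO_COLS = ("ICP", "gallstone", "cholangiocarcinoma", "cirrhosis", "neoplasm")


def render_summary(
    all_records: Iterable[VariantRecord],
    included: Iterable[VariantRecord],
    verdicts: Mapping[str, acmg.Verdict] | None = None,
    burden_p: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One row per registry gene; tallies are column sums of the row-level data."""
    all_records = list(all_records)
    included = list(included)
    verdicts = verdicts or {}
    burden_p = burden_p or {}
    pheno = genotype_phenotype_counts(included)
    total = Counter(r.gene for r in all_records)
    kept = Counter(r.gene for r in included)
    verdict_tally: dict[str, Counter] = {}
    for rec in included:
        v = verdicts.get(rec.variant_id)
        if v is not None:
            verdict_tally.setdefault(rec.gene, Counter())[v.tier] += 1

    rows = []
    for gene in gene_registry():
        g = gene.symbol
        row = {
            "gene": g,
            "n_variants": total.get(g, 0),
            "n_included": kept.get(g, 0),
        }
        for tier, col in _VERDICT_COLS.items():
            row[col] = verdict_tally.get(g, Counter()).get(tier, 0)
        for group in _PHENO_COLS:
            row[f"pheno_{group}"] = pheno.get(g, Counter()).get(group, 0)
        if g in burden_p:
            row["burden_p"] = burden_p[g]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def summary_to_markdown(summary: pd.DataFrame) -> str:
    return summary.to_markdown()
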