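"""Synthetic cohort generator with full ground-truth bookkeeping.

Emulates the statistical structure the pipeline assumes: a cohort of
unrelated volunteers (default 5,236) with rare-variant genotypes drawn under
Hardy-Weinberg equilibrium at allele frequencies log-uniform over
[1e-4, 0.05], binary ICP case status assigned through a logistic link on the
per-gene collapsed carrier indicator (intercept solved numerically from the
target prevalence, default 1.54%), and total serum bile-acid values drawn
log-normal with the case location shifted so that 90% of cases exceed the
10 umol/L diagnostic threshold. A configurable fraction of variants (default
34%) is cohort-private, i.e. carries no gnomAD frequency.

Everything derives from a single seed; identical configs produce bit-identical
output files.
"""
from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from cholevar import core
from cholevar.core import (
    GenotypeMatrix,
    PhenotypeRecord,
    PredictorPanel,
    VariantRecord,
)

__all__ = ["SimConfig", "GroundTruth", "SimResult", "generate",
           "plant_co_carriers", "emit_table_fixtures"]

_AMINO = "ARNDCQEGHILKMFPSTWYV"

_PATHOGENIC_CODE_SETS = (
    ("PVS1", "PM2"),
    ("PVS1", "PM2", "PP3"),
    ("PM1", "PM2", "PP2", "PP3"),
)
_BENIGN_CODE_SETS = (
    ("PM2", "PP2", "BP4"),
    ("BP4", "BP6"),
    ("PM2", "PP2"),
    ("BA1", "BP4"),
)

# deleterious-score regions per tool (cutoffs from the prioritize defaults)
_SCORE_REGIONS = {
    "polyphen": ((0.446, 1.0), (0.0, 0.446)),
    "sift": ((0.0, 0.05), (0.05, 1.0)),
    "cadd": ((20.0, 40.0), (0.0, 20.0)),
    "revel": ((0.5, 1.0), (0.0, 0.5)),
    "mcap": ((0.025, 1.0), (0.0, 0.025)),
}


@dataclass
class SimConfig:
    """Study-condition parameters for the generator."""

    n_samples: int = 5236
    seed: int = 0
    variants_per_gene: int = 30
    af_range: tuple[float, float] = (1e-4, 0.05)
    fraction_private: float = 0.34
    prevalence: float = 0.0154
    case_label: str = "ICP"
    carrier_or: dict[str, float] = field(default_factory=dict)  # gene -> OR
    rare_af_threshold: float = 0.01  # carrier definition for the case model
    female_fraction: float = 0.60
    tsba_sigma: float = 0.6
    tsba_case_exceed: float = 0.90   # P(case TSBA >= diagnostic threshold)
    tsba_control_exceed: float = 0.05
    tsba_diagnostic: float = 10.0
    ba_missing_fraction: float = 0.10
    pathogenic_fraction: float = 0.25
    p_deleterious_pathogenic: float = 0.95
    p_deleterious_benign: float = 0.15
    p_predictor_missing: float = 0.05
    literature_fraction: float = 0.20
    icd10_code: str = "O26.6"
    genotypes_only: bool = False  # skip phenotype/annotation synthesis

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        for g, o in self.carrier_or.items():
            if o < 0:
                raise ValueError(f"odds ratio for {g} must be >= 0")


@dataclass
class GroundTruth:
    true_af: dict[str, float]
    planted_pathogenic: list[str]
    planted_inclusion: dict[str, bool]
    case_status: dict[str, bool]
    carrier_sets: dict[str, list[str]]  # gene -> carrier sample ids
    co_carrier_groups: list[list[str]]
    degenerate: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class SimResult:
    config: SimConfig
    matrix: GenotypeMatrix
    records: list[VariantRecord]
    phenotypes: list[PhenotypeRecord]
    truth: GroundTruth
    sites: dict[str, tuple[str, int, str, str]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "annotations": outdir / "annotations.tsv",
            "phenotypes": outdir / "phenotypes.tsv",
            "truth": outdir / "truth.json",
        }
        core.write_vcf(self.matrix, paths["vcf"], sites=self.sites)
        core.write_annotation_table(self.records, paths["annotations"])
        core.write_phenotype_table(self.phenotypes, paths["phenotypes"])
        self.truth.to_json(paths["truth"])
        return paths


def _mu_for_exceedance(threshold: float, sigma: float, p_exceed: float) -> float:
    # log-normal location such that P(X >= threshold) = p_exceed
    return float(np.log(threshold) + sigma * norm.ppf(p_exceed))


def _draw_panel(rng: np.random.Generator, p_del: float, p_missing: float) -> tuple[PredictorPanel, bool]:
    kwargs = {}
    unanimous = True
    for tool in core.PREDICTOR_TOOLS:
        if rng.random() < p_missing:
            kwargs[tool] = None
            unanimous = False
            continue
        deleterious = rng.random() < p_del
        if tool in ("metalr", "metasvm"):
            kwargs[tool] = "D" if deleterious else "T"
        else:
            lo, hi = _SCORE_REGIONS[tool][0 if deleterious else 1]
            kwargs[tool] = float(rng.uniform(lo, hi))
        unanimous &= deleterious
    return PredictorPanel(**kwargs), unanimous


def generate(config: SimConfig | None = None) -> SimResult:
    """Produce a cohort (genotypes + annotations + phenotypes) with ground truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genes = [g.symbol for g in core.gene_registry()]
    chrom_of = {
        g.symbol: g.chromosome_band.split("q")[0].split("p")[0]
        for g in core.gene_registry()
    }
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]

    # --- variants and genotypes under HWE -------------------------------
    lo, hi = config.af_range
    keys: list[str] = []
    gene_of: list[str] = []
    afs: list[float] = []
    sites: dict[str, tuple[str, int, str, str]] = {}
    for gene in genes:
        for v in range(config.variants_per_gene):
            pos = v + 1
            label = (
                f"{_AMINO[int(rng.integers(20))]}{100 + v}"
                f"{_AMINO[int(rng.integers(20))]}"
            )
            key = f"{gene}:{label}"
            if key in sites:  # same-residue collision within a gene
                key = f"{gene}:{label}.{v}"
            keys.append(key)
            gene_of.append(gene)
            afs.append(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            sites[key] = (chrom_of[gene], 1_000_000 + 100 * v, "A", "G")
    af_arr = np.array(afs)
    counts = rng.binomial(2, af_arr[None, :], size=(n, len(keys))).astype(np.int8)
    matrix = GenotypeMatrix(sample_ids, keys, counts)

    # --- case status via logistic link on rare-carrier indicators -------
    rare = af_arr <= config.rare_af_threshold
    carrier_by_gene = {}
    for gene in genes:
        cols = [j for j, g in enumerate(gene_of) if g == gene and rare[j]]
        carrier_by_gene[gene] = (
            (counts[:, cols] >= 1).any(axis=1)
            if cols
            else np.zeros(n, dtype=bool)
        )
    eta = np.zeros(n)
    degenerate = False
    for gene, odds in config.carrier_or.items():
        if odds <= 0:
            raise ValueError(f"odds ratio for {gene} must be > 0")
        if not carrier_by_gene[gene].any():
            degenerate = True
            import warnings

            warnings.warn(
                f"{gene}: planted OR {odds} but no expected carriers; "
                "enrichment is inert for this seed",
                stacklevel=2,
            )
        eta += np.log(odds) * carrier_by_gene[gene]

    def mean_risk(b0: float) -> float:
        return float(expit(b0 + eta).mean())

    b0 = brentq(lambda b: mean_risk(b) - config.prevalence, -30.0, 10.0)
    case = rng.random(n) < expit(b0 + eta)

    if config.genotypes_only:
        truth = GroundTruth(
            true_af={k: float(a) for k, a in zip(keys, af_arr)},
            planted_pathogenic=[],
            planted_inclusion={},
            case_status={s: bool(c) for s, c in zip(sample_ids, case)},
            carrier_sets={
                g: [sample_ids[i] for i in np.flatnonzero(v)]
                for g, v in carrier_by_gene.items()
            },
            co_carrier_groups=[],
            degenerate=degenerate,
        )
        return SimResult(config, matrix, [], [], truth, sites)

    # --- sex, ICD codes, bile acids -------------------------------------
    n_cases = int(case.sum())
    sex = np.full(n, "M", dtype=object)
    sex[case] = "F"  # gestational disease: cases are female
    remaining = max(0.0, config.female_fraction * n - n_cases)
    p_f = remaining / max(1, n - n_cases)
    sex[~case] = np.where(rng.random(n - n_cases) < p_f, "F", "M")

    mu_case = _mu_for_exceedance(
        config.tsba_diagnostic, config.tsba_sigma, config.tsba_case_exceed
    )
    mu_ctrl = _mu_for_exceedance(
        config.tsba_diagnostic, config.tsba_sigma, config.tsba_control_exceed
    )
    ba_missing = rng.random(n) < config.ba_missing_fraction
    phenotypes = []
    for i, sid in enumerate(sample_ids):
        if ba_missing[i]:
            tsba = ()
        else:
            k = int(rng.integers(1, 4)) if case[i] else 1
            mu = mu_case if case[i] else mu_ctrl
            tsba = tuple(
                (float(np.round(np.exp(rng.normal(mu, config.tsba_sigma)), 1)), "")
                for _ in range(k)
            )
        phenotypes.append(
            PhenotypeRecord(
                sample_id=sid,
                sex=str(sex[i]),
                icd10_codes=frozenset({config.icd10_code}) if case[i] else frozenset(),
                tsba_measurements=tsba,
                icp_verified=bool(case[i]),
            )
        )

    # --- annotation records with planted prioritization criteria --------
    pathogenic = rng.random(len(keys)) < config.pathogenic_fraction
    private = rng.random(len(keys)) < config.fraction_private
    literature = rng.random(len(keys)) < config.literature_fraction
    case_idx = np.flatnonzero(case)
    records = []
    planted_inclusion = {}
    for j, key in enumerate(keys):
        panel, unanimous = _draw_panel(
            rng,
            config.p_deleterious_pathogenic if pathogenic[j] else config.p_deleterious_benign,
            config.p_predictor_missing,
        )
        carried_by_case = bool((counts[case_idx, j] >= 1).any())
        groups = frozenset({config.case_label}) if (carried_by_case and pathogenic[j]) else frozenset()
        code_pool = _PATHOGENIC_CODE_SETS if pathogenic[j] else _BENIGN_CODE_SETS
        codes = frozenset(code_pool[int(rng.integers(len(code_pool)))])
        af_gnomad = None
        if not private[j]:
            af_gnomad = float(
                np.clip(af_arr[j] * rng.lognormal(0.0, 0.3), 0.0, 1.0)
            )
        gene, label = key.split(":", 1)
        records.append(
            VariantRecord(
                gene=gene,
                protein_change=label,
                consequence_label="missense",
                af_gnomad=af_gnomad,
                af_cohort=float(af_arr[j]),
                predictor_panel=panel,
                literature_known=bool(literature[j]),
                acmg_codes=codes,
                phenotype_groups=groups,
            )
        )
        # generator-side bookkeeping of the 4-way OR rule + MAF gate
        any_criterion = bool(groups) or bool(literature[j]) or private[j] or unanimous
        maf = af_gnomad if af_gnomad is not None else float(af_arr[j])
        maf_pass = maf < 0.05
        planted_inclusion[key] = bool(
            any_criterion and (maf_pass or bool(groups))
        )

    truth = GroundTruth(
        true_af={k: float(a) for k, a in zip(keys, af_arr)},
        planted_pathogenic=[k for k, p in zip(keys, pathogenic) if p],
        planted_inclusion=planted_inclusion,
        case_status={s: bool(c) for s, c in zip(sample_ids, case)},
        carrier_sets={
            g: [sample_ids[i] for i in np.flatnonzero(v)]
            for g, v in carrier_by_gene.items()
        },
        co_carrier_groups=[],
        degenerate=degenerate,
    )
    return SimResult(config, matrix, records, phenotypes, truth, sites)


def plant_co_carriers(
    result: SimResult, variant_keys: list[str], sample_ids: list[str]
) -> None:
    """Force the given variants to be carried by exactly the given samples.

    Mirrors a linkage-disequilibrium-like observation: k >= 2 variants
    heterozygous in the same m >= 1 volunteers and absent elsewhere.
    """
    if len(variant_keys) < 2:
        raise ValueError("need at least 2 variants to plant a co-carrier group")
    if len(sample_ids) < 1:
        raise ValueError("a co-carrier group needs at least 1 carrier")
    missing = set(sample_ids) - set(result.matrix.sample_ids)
    if missing:
        raise ValueError(f"unknown sample id(s): {sorted(missing)}")
    rows = [result.matrix.sample_ids.index(s) for s in sample_ids]
    for key in variant_keys:
        j = result.matrix.variant_keys.index(key)
        result.matrix.counts[:, j] = 0
        result.matrix.counts[rows, j] = 1
    result.truth.co_carrier_groups.append(sorted(variant_keys))


def emit_table_fixtures(outdir: str | Path) -> list[Path]:
    """Copy the packaged in-print table fixtures to ``outdir``, byte-stable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = []
    for name in (
        "gene_panel.tsv",
        "phenotype_associated_variants.tsv",
        "lof_variants.tsv",
        "icp_case_reports.tsv",
    ):
        dest = outdir / name
        shutil.copyfile(core.fixture_path(name), dest)
        out.append(dest)
    return out
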