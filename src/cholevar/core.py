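"""Domain types, gene registry and file I/O for the candidate-gene pipeline.

The analysis is identity-keyed: every variant is addressed as
``"GENE:protein_change"`` (cDNA label fallback for splice variants such as
``"ABCB11:c.2611-2A>T"``), never by genomic coordinate arithmetic.  VCF
positions are carried through 1-based and untouched.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHENOTYPE_VOCABULARY",
    "PREDICTOR_TOOLS",
    "GeneInfo",
    "PredictorPanel",
    "VariantRecord",
    "GenotypeMatrix",
    "PhenotypeRecord",
    "IcpCaseReportRow",
    "VcfFormatError",
    "AnnotationError",
    "gene_registry",
    "gene_info",
    "read_vcf",
    "write_vcf",
    "read_annotation_table",
    "write_annotation_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "carrier_and_allele_counts",
    "load_gene_panel",
    "load_phenotype_variant_table",
    "load_lof_variant_table",
    "load_icp_case_table",
    "fixture_path",
]

#: Controlled vocabulary for EHR-derived phenotype groups attached to variants.
PHENOTYPE_VOCABULARY = frozenset(
    {"ICP", "gallstone", "cholangiocarcinoma", "cirrhosis", "neoplasm", "none"}
)

#: The seven in-silico deleteriousness predictors used for the consensus rule.
PREDICTOR_TOOLS = ("polyphen", "sift", "cadd", "revel", "metalr", "metasvm", "mcap")

ANNOTATION_COLUMNS = [
    "gene", "transcript", "protein_change", "cdna_change", "dbsnp",
    "consequence", "af_gnomad", "af_cohort", "polyphen", "sift", "cadd",
    "revel", "metalr", "metasvm", "mcap", "literature_known", "clinvar",
    "acmg_codes", "phenotype_groups", "zygosity", "het_n", "hom_n", "verdict",
]


class VcfFormatError(ValueError):
    """Raised for malformed VCF input (message names the offending line)."""


class AnnotationError(ValueError):
    """Raised when an annotation or phenotype table violates its contract."""


@dataclass(frozen=True)
class GeneInfo:
    """One candidate gene: a canalicular transporter or its regulator."""

    symbol: str
    chromosome_band: str
    product: str
    omim_id: int
    exons: int
    length_kb: float
    associated_disease: str

    def __post_init__(self) -> None:
        if self.exons <= 0 or self.length_kb <= 0:
            raise ValueError(f"{self.symbol}: exons and length_kb must be positive")


@dataclass(frozen=True)
class PredictorPanel:
    """Score-or-call slots for the seven in-silico predictors.

    Numeric slots hold the tool's native score (PolyPhen-2/SIFT/REVEL/M-CAP in
    [0, 1], CADD on the phred scale); MetaLR/MetaSVM may carry either a score
    or the categorical "D"/"T" call. ``None`` marks a missing slot.
    """

    polyphen: float | None = None
    sift: float | None = None
    cadd: float | None = None
    revel: float | None = None
    metalr: float | str | None = None
    metasvm: float | str | None = None
    mcap: float | None = None

    def __post_init__(self) -> None:
        for tool in ("polyphen", "sift", "revel", "mcap"):
            v = getattr(self, tool)
            if v is not None and not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{tool} score {v} outside [0, 1]")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"cadd phred score {self.cadd} negative")

    def get(self, tool: str):
        if tool not in PREDICTOR_TOOLS:
            raise KeyError(f"unknown predictor tool {tool!r}")
        return getattr(self, tool)

    def n_missing(self) -> int:
        return sum(self.get(t) is None for t in PREDICTOR_TOOLS)


@dataclass
class VariantRecord:
    """One annotated variant row (identity, frequencies, evidence, phenotypes)."""

    gene: str
    protein_change: str = ""
    transcript_id: str = ""
    cdna_change: str = ""
    dbsnp: str = ""
    consequence_label: str = ""
    af_gnomad: float | None = None
    af_cohort: float | None = None
    predictor_panel: PredictorPanel = field(default_factory=PredictorPanel)
    literature_known: bool = False
    clinvar_label: str = ""
    acmg_codes: frozenset[str] = frozenset()
    printed_verdict: str = ""
    phenotype_groups: frozenset[str] = frozenset()
    zygosity_observed: str = "het"
    het_count: int | None = None
    hom_count: int | None = None
    consequence_class: "object | None" = None  # filled by cholevar.consequence

    def __post_init__(self) -> None:
        for name in ("af_gnomad", "af_cohort"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise AnnotationError(
                    f"{self.variant_id}: {name} = {v} outside [0, 1]"
                )
        bad = set(self.phenotype_groups) - PHENOTYPE_VOCABULARY
        if bad:
            raise AnnotationError(
                f"{self.variant_id}: unknown phenotype label(s) {sorted(bad)}; "
                f"allowed: {sorted(PHENOTYPE_VOCABULARY)}"
            )

    @property
    def variant_id(self) -> str:
        label = self.protein_change or self.cdna_change or self.transcript_id
        return f"{self.gene}:{label}"

    @property
    def has_phenotype(self) -> bool:
        return bool(self.phenotype_groups - {"none"})


class CarrierCounts(NamedTuple):
    het_count: int
    hom_count: int
    allele_count: int
    carrier_count: int


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele-count matrix.

    ``counts[i, j]`` is the number of alternate alleles sample ``i`` carries at
    variant ``j`` (0, 1 or 2); ``-1`` marks a missing genotype, which is
    excluded from both numerator and denominator of the derived allele
    frequency.
    """

    sample_ids: list[str]
    variant_keys: list[str]
    counts: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )
        valid = np.isin(self.counts, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("allele counts must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-variant AF = alt alleles / (2 x called samples); NaN if none called."""
        called = self.counts >= 0
        n_called = called.sum(axis=0)
        alt = np.where(called, self.counts, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def column(self, variant_key: str) -> np.ndarray:
        try:
            j = self.variant_keys.index(variant_key)
        except ValueError:
            raise KeyError(f"variant {variant_key!r} not in matrix") from None
        return self.counts[:, j]

    def subset(self, variant_keys: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_keys.index(k) for k in variant_keys]
        return GenotypeMatrix(
            list(self.sample_ids), list(variant_keys), self.counts[:, idx].copy()
        )


@dataclass
class PhenotypeRecord:
    """One sample's EHR-derived labels and bile-acid measurements."""

    sample_id: str
    sex: str = "unknown"  # F | M | unknown
    icd10_codes: frozenset[str] = frozenset()
    tsba_measurements: tuple[tuple[float, str], ...] = ()
    icp_verified: bool = False
    phenotype_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for value, _tag in self.tsba_measurements:
            if value < 0:
                raise AnnotationError(
                    f"{self.sample_id}: negative TSBA measurement {value}"
                )

    @property
    def highest_tsba(self) -> float | None:
        if not self.tsba_measurements:
            return None
        return max(v for v, _ in self.tsba_measurements)


@dataclass
class IcpCaseReportRow:
    """One ICP case: volunteer id, peak bile acids, and carried variants."""

    volunteer_id: str
    highest_tsba: float | None
    variants: list[tuple[str, str, str, str]]  # (gene, label, zygosity, type)

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"volunteer {self.volunteer_id}: no carried variants")


# ---------------------------------------------------------------------------
# Gene registry
# ---------------------------------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path to a packaged fixture TSV."""
    return Path(resources.files("cholevar").joinpath("data", name))


def _registry() -> dict[str, GeneInfo]:
    df = pd.read_csv(fixture_path("gene_panel.tsv"), sep="\t", dtype=str)
    out = {}
    for r in df.itertuples(index=False):
        out[r.symbol] = GeneInfo(
            symbol=r.symbol,
            chromosome_band=r.chromosome_band,
            product="" if pd.isna(r.product) else r.product,
            omim_id=int(r.omim_id),
            exons=int(r.exons),
            length_kb=float(r.length_kb),
            associated_disease=r.associated_disease,
        )
    return out


def gene_registry() -> list[GeneInfo]:
    """The five packaged candidate genes, in panel order."""
    return list(_registry().values())


def gene_info(symbol: str) -> GeneInfo:
    reg = _registry()
    if symbol not in reg:
        raise KeyError(
            f"unknown gene {symbol!r}; panel: {', '.join(reg)}"
        )
    return reg[symbol]


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT genotypes into a GenotypeMatrix.

    Multiallelic records are split into one matrix row per alternate allele;
    the per-alt allele count for a sample is the number of haplotypes carrying
    that alt. A genotype containing any no-call allele is recorded as missing.
    Variant keys come from the ID column (unique suffix appended for the split
    alts of a shared ID), falling back to ``chrom:pos:ref:alt``.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad input
        raise VcfFormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    if not _header_has_gt(path):
        vcf.close()
        raise VcfFormatError(f"{path}: no GT FORMAT field declared in header")

    sample_ids = list(vcf.samples)
    keys: list[str] = []
    cols: list[np.ndarray] = []
    seen: dict[str, int] = {}
    for line_no, variant in enumerate(vcf, start=1):
        gts = variant.genotype.array()  # (n_samples, ploidy+1); last col = phase
        alleles = gts[:, :-1]
        missing = (alleles < 0).any(axis=1)
        for alt_idx, alt in enumerate(variant.ALT, start=1):
            counts = (alleles == alt_idx).sum(axis=1).astype(np.int8)
            counts[missing] = -1
            base = variant.ID or f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}"
            if len(variant.ALT) > 1 and variant.ID:
                base = f"{base}:{alt}"
            if base in seen:
                seen[base] += 1
                base = f"{base}.{seen[base]}"
            else:
                seen[base] = 0
            keys.append(base)
            cols.append(counts)
    vcf.close()
    counts = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, keys, counts)


def _header_has_gt(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                return False
            if line.startswith("##FORMAT=<ID=GT"):
                return True
    return False


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    *,
    sites: dict[str, tuple[str, int, str, str]] | None = None,
) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes.

    ``sites`` optionally maps variant key -> (chrom, pos, ref, alt); without it
    synthetic single-base sites on chromosome ``.`` are emitted, one per
    variant, preserving genotype content (het -> 0/1, hom-alt -> 1/1,
    missing -> ./.).
    """
    gt_code = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = sorted(
        {sites[k][0] for k in matrix.variant_keys if sites and k in sites} or {"."}
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, key in enumerate(matrix.variant_keys):
            chrom, pos, ref, alt = (
                sites[key] if sites and key in sites else (".", j + 1, "A", "T")
            )
            gts = "\t".join(gt_code[int(c)] for c in matrix.counts[:, j])
            fh.write(f"{chrom}\t{pos}\t{key}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Annotation / phenotype tables
# ---------------------------------------------------------------------------

def _parse_float(cell, what: str, row_id: str) -> float | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise AnnotationError(f"{row_id}: cannot parse {what} value {cell!r}")


def _parse_panel(rec: dict, row_id: str) -> PredictorPanel:
    kwargs = {}
    for tool in PREDICTOR_TOOLS:
        cell = rec.get(tool, "")
        if cell in ("", None) or (isinstance(cell, float) and np.isnan(cell)):
            kwargs[tool] = None
        elif tool in ("metalr", "metasvm") and str(cell).upper() in ("D", "T"):
            kwargs[tool] = str(cell).upper()
        else:
            kwargs[tool] = _parse_float(cell, tool, row_id)
    return PredictorPanel(**kwargs)


def read_annotation_table(path: str | Path) -> list[VariantRecord]:
    """Parse an annotation TSV into typed records.

    Missing AF cells map to ``None`` (unknown), never 0. Unknown phenotype
    labels raise :class:`AnnotationError` listing the allowed vocabulary.
    """
    from cholevar import acmg  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene", "protein_change") if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing required column(s) {missing}")
    records: list[VariantRecord] = []
    seen_ids: set[str] = set()
    for rec in df.to_dict(orient="records"):
        row_id = f"{rec.get('gene', '?')}:{rec.get('protein_change', '?')}"
        groups = frozenset(
            g.strip()
            for g in str(rec.get("phenotype_groups", "")).split(";")
            if g.strip()
        )
        codes = acmg.parse_codes(rec.get("acmg_codes", ""))
        record = VariantRecord(
            gene=rec["gene"],
            protein_change=rec.get("protein_change", ""),
            transcript_id=rec.get("transcript", ""),
            cdna_change=rec.get("cdna_change", ""),
            dbsnp=rec.get("dbsnp", ""),
            consequence_label=rec.get("consequence", ""),
            af_gnomad=_parse_float(rec.get("af_gnomad", ""), "af_gnomad", row_id),
            af_cohort=_parse_float(rec.get("af_cohort", ""), "af_cohort", row_id),
            predictor_panel=_parse_panel(rec, row_id),
            literature_known=str(rec.get("literature_known", "false")).lower()
            in ("true", "1", "yes"),
            clinvar_label=rec.get("clinvar", ""),
            acmg_codes=codes,
            printed_verdict=rec.get("verdict", ""),
            phenotype_groups=groups,
            zygosity_observed=rec.get("zygosity", "het") or "het",
            het_count=(int(rec["het_n"]) if rec.get("het_n") else None),
            hom_count=(int(rec["hom_n"]) if rec.get("hom_n") else None),
        )
        if record.variant_id in seen_ids:
            raise AnnotationError(f"duplicate variant_id {record.variant_id}")
        seen_ids.add(record.variant_id)
        records.append(record)
    return records


def write_annotation_table(
    records: Iterable[VariantRecord], path: str | Path, extra: dict | None = None
) -> None:
    """Write records back to the fixed-header annotation TSV.

    ``extra`` maps column name -> {variant_id: value} for appended columns
    (e.g. consequence_class, included, reasons, engine_verdict).
    """
    extra = extra or {}
    cols = ANNOTATION_COLUMNS + list(extra)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in records:
            base = [
                r.gene, r.transcript_id, r.protein_change, r.cdna_change,
                r.dbsnp, r.consequence_label,
                "" if r.af_gnomad is None else repr(r.af_gnomad),
                "" if r.af_cohort is None else repr(r.af_cohort),
            ]
            base += [
                "" if r.predictor_panel.get(t) is None else str(r.predictor_panel.get(t))
                for t in PREDICTOR_TOOLS
            ]
            base += [
                "true" if r.literature_known else "false",
                r.clinvar_label,
                ",".join(sorted(r.acmg_codes)),
                ";".join(sorted(r.phenotype_groups)),
                r.zygosity_observed,
                "" if r.het_count is None else str(r.het_count),
                "" if r.hom_count is None else str(r.hom_count),
                r.printed_verdict,
            ]
            base += [str(extra[c].get(r.variant_id, "")) for c in extra]
            w.writerow(base)


def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    """Phenotype TSV: sample_id, sex, icd10 (;-sep), tsba (;-sep), icp_verified."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    seen = set()
    for rec in df.to_dict(orient="records"):
        sid = rec["sample_id"]
        if sid in seen:
            raise AnnotationError(f"duplicate sample_id {sid}")
        seen.add(sid)
        tsba = tuple(
            (float(tok), "")
            for tok in str(rec.get("tsba", "")).split(";")
            if tok.strip()
        )
        records.append(
            PhenotypeRecord(
                sample_id=sid,
                sex=rec.get("sex", "unknown") or "unknown",
                icd10_codes=frozenset(
                    c.strip() for c in str(rec.get("icd10", "")).split(";") if c.strip()
                ),
                tsba_measurements=tsba,
                icp_verified=str(rec.get("icp_verified", "false")).lower()
                in ("true", "1", "yes"),
            )
        )
    return records


def write_phenotype_table(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "sex", "icd10", "tsba", "icp_verified"])
        for r in records:
            w.writerow(
                [
                    r.sample_id,
                    r.sex,
                    ";".join(sorted(r.icd10_codes)),
                    ";".join(repr(v) for v, _ in r.tsba_measurements),
                    "true" if r.icp_verified else "false",
                ]
            )


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def carrier_and_allele_counts(genotypes: Sequence[int] | np.ndarray) -> CarrierCounts:
    """Tally het/hom carriers and alleles from a per-sample allele-count vector.

    carrier_count = het + hom; allele_count = het + 2*hom. Missing (-1)
    genotypes are ignored.
    """
    g = np.asarray(genotypes)
    het = int((g == 1).sum())
    hom = int((g == 2).sum())
    return CarrierCounts(het, hom, het + 2 * hom, het + hom)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def load_gene_panel() -> pd.DataFrame:
    return pd.read_csv(fixture_path("gene_panel.tsv"), sep="\t")


def load_phenotype_variant_table() -> list[VariantRecord]:
    """Phenotype-associated non-synonymous variants of the five genes."""
    return read_annotation_table(fixture_path("phenotype_associated_variants.tsv"))


def load_lof_variant_table() -> list[VariantRecord]:
    """The 14 loss-of-function variants of the five genes."""
    return read_annotation_table(fixture_path("lof_variants.tsv"))


def load_icp_case_table() -> list[IcpCaseReportRow]:
    """Per-volunteer ICP case reports (carried variants + peak TSBA)."""
    df = pd.read_csv(fixture_path("icp_case_reports.tsv"), sep="\t", dtype=str,
                     keep_default_na=False)
    rows: dict[str, IcpCaseReportRow] = {}
    for rec in df.to_dict(orient="records"):
        vid = rec["volunteer_id"]
        tsba = float(rec["highest_tsba"]) if rec["highest_tsba"] else None
        entry = (rec["gene"], rec["variant"], rec["zygosity"], rec["type"])
        if vid in rows:
            rows[vid].variants.append(entry)
        else:
            rows[vid] = IcpCaseReportRow(vid, tsba, [entry])
    return list(rows.values())
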