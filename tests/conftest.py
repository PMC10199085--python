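import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cholevar import consequence, core, synthetic


@pytest.fixture(scope="session")
def nsv_records():
    return consequence.classify_all(core.load_phenotype_variant_table())


@pytest.fixture(scope="session")
def lof_records():
    return consequence.classify_all(core.load_lof_variant_table())


@pytest.fixture(scope="session")
def icp_rows():
    return core.load_icp_case_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-sample cohort with modest per-gene variant counts, seed-fixed."""
    cfg = synthetic.SimConfig(n_samples=400, seed=11, variants_per_gene=8)
    return synthetic.generate(cfg)


def make_vcf(path, body, samples=("A", "B")):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    Path(path).write_text(header + body)
    return path
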