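"""Synthetic cohort generator: reproducibility, HWE, calibration hooks."""
import hashlib
import warnings

import numpy as np
import pytest

from cholevar.burden import co_carrier_groups
from cholevar.synthetic import (
    SimConfig,
    emit_table_fixtures,
    generate,
    plant_co_carriers,
)


def file_hashes(result, outdir):
    paths = result.write(outdir)
    return {k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()}


class TestReproducibility:
    def test_same_seed_same_file_hashes(self, tmp_path):
        cfg = SimConfig(n_samples=200, seed=42, variants_per_gene=5)
        h1 = file_hashes(generate(cfg), tmp_path / "a")
        h2 = file_hashes(generate(cfg), tmp_path / "b")
        assert h1 == h2

    def test_different_seed_differs(self, tmp_path):
        h1 = file_hashes(
            generate(SimConfig(n_samples=200, seed=1, variants_per_gene=5)),
            tmp_path / "a",
        )
        h2 = file_hashes(
            generate(SimConfig(n_samples=200, seed=2, variants_per_gene=5)),
            tmp_path / "b",
        )
        assert h1["vcf"] != h2["vcf"]


class TestStatisticalStructure:
    def test_af_recovery_within_binomial_bounds(self):
        res = generate(SimConfig(n_samples=4000, seed=3, genotypes_only=True))
        emp = res.matrix.alt_allele_frequency()
        for j, key in enumerate(res.matrix.variant_keys):
            q = res.truth.true_af[key]
            sigma = np.sqrt(q * (1 - q) / (2 * res.matrix.n_samples))
            assert abs(emp[j] - q) <= 4 * sigma + 1e-12, key

    def test_hwe_hom_alt_fraction(self):
        # AF 0.3 -> hom-alt fraction q^2 = 0.09
        rng_cfg = SimConfig(
            n_samples=10_000, seed=9, variants_per_gene=1,
            af_range=(0.3, 0.3000001), genotypes_only=True,
        )
        res = generate(rng_cfg)
        hom_frac = (res.matrix.counts == 2).mean(axis=0)
        sigma = np.sqrt(0.09 * 0.91 / 10_000)
        assert np.all(np.abs(hom_frac - 0.09) <= 3.5 * sigma)

    def test_case_count_near_prevalence(self):
        cfg = SimConfig(seed=7, genotypes_only=True)  # n=5236, prevalence 1.54%
        res = generate(cfg)
        n_cases = sum(res.truth.case_status.values())
        expected = cfg.n_samples * cfg.prevalence
        bound = 3 * np.sqrt(cfg.n_samples * cfg.prevalence * (1 - cfg.prevalence))
        assert abs(n_cases - expected) <= bound

    def test_null_carrier_fractions_balanced(self):
        # OR = 1: carrier fraction among cases == controls up to sampling error
        diffs = []
        for seed in range(40):
            res = generate(
                SimConfig(n_samples=500, seed=seed, prevalence=0.5,
                          genotypes_only=True)
            )
            cases = np.array(
                [res.truth.case_status[s] for s in res.matrix.sample_ids]
            )
            carrier = np.zeros(len(cases), dtype=bool)
            for ids in res.truth.carrier_sets.values():
                carrier |= np.isin(res.matrix.sample_ids, ids)
            diffs.append(carrier[cases].mean() - carrier[~cases].mean())
        assert abs(np.mean(diffs)) < 0.02

    def test_planted_or_enriches_cases(self):
        res = generate(
            SimConfig(n_samples=3000, seed=5, prevalence=0.5,
                      carrier_or={"ABCB11": 8.0}, genotypes_only=True)
        )
        cases = np.array([res.truth.case_status[s] for s in res.matrix.sample_ids])
        carrier = np.isin(
            res.matrix.sample_ids, res.truth.carrier_sets["ABCB11"]
        )
        assert carrier[cases].mean() > carrier[~cases].mean()


class TestPhenotypeModel:
    def test_case_tsba_mostly_above_diagnostic_threshold(self):
        res = generate(SimConfig(n_samples=1000, seed=21, prevalence=0.2,
                                 variants_per_gene=4))
        cases = [
            p for p in res.phenotypes
            if res.truth.case_status[p.sample_id] and p.tsba_measurements
        ]
        controls = [
            p for p in res.phenotypes
            if not res.truth.case_status[p.sample_id] and p.tsba_measurements
        ]
        assert len(cases) > 100
        case_frac = np.mean([p.highest_tsba >= 10 for p in cases])
        ctrl_frac = np.mean([p.highest_tsba >= 10 for p in controls])
        # locations calibrated to 0.90 / 0.05 exceedance
        assert abs(case_frac - 0.90) <= 0.08
        assert ctrl_frac <= 0.12

    def test_cases_carry_diagnosis_code_and_sex(self, small_cohort):
        for p in small_cohort.phenotypes:
            if small_cohort.truth.case_status[p.sample_id]:
                assert "O26.6" in p.icd10_codes
                assert p.sex == "F"
                assert p.icp_verified


class TestPlantCoCarriers:
    def test_planted_group_recovered(self, tmp_path):
        res = generate(SimConfig(n_samples=100, seed=13, variants_per_gene=4))
        keys = res.matrix.variant_keys[:3]
        samples = res.matrix.sample_ids[:3]
        plant_co_carriers(res, list(keys), list(samples))
        groups = co_carrier_groups(res.matrix)
        assert sorted(keys) in [sorted(g) for g in groups]
        assert res.truth.co_carrier_groups == [sorted(keys)]

    def test_zero_carriers_rejected(self):
        res = generate(SimConfig(n_samples=50, seed=13, variants_per_gene=4))
        with pytest.raises(ValueError, match="at least 1"):
            plant_co_carriers(res, res.matrix.variant_keys[:2], [])

    def test_two_disjoint_groups_not_merged(self):
        res = generate(SimConfig(n_samples=100, seed=13, variants_per_gene=4))
        k = res.matrix.variant_keys
        s = res.matrix.sample_ids
        plant_co_carriers(res, [k[0], k[1]], [s[0], s[1]])
        plant_co_carriers(res, [k[2], k[3]], [s[2]])
        groups = [sorted(g) for g in co_carrier_groups(res.matrix)]
        assert sorted([k[0], k[1]]) in groups
        assert sorted([k[2], k[3]]) in groups

    def test_single_variant_rejected(self):
        res = generate(SimConfig(n_samples=50, seed=13, variants_per_gene=4))
        with pytest.raises(ValueError, match="at least 2"):
            plant_co_carriers(res, res.matrix.variant_keys[:1], ["S00000"])


class TestDegenerateConfig:
    def test_or_without_carriers_warns(self):
        cfg = SimConfig(
            n_samples=20, seed=1, variants_per_gene=1,
            af_range=(1e-6, 2e-6),  # essentially no carriers expected
            carrier_or={"ABCB11": 4.0}, genotypes_only=True,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = generate(cfg)
        assert res.truth.degenerate
        assert any("inert" in str(w.message) for w in caught)


def test_emitted_fixtures_are_byte_stable(tmp_path):
    first = {p.name: p.read_bytes() for p in emit_table_fixtures(tmp_path / "a")}
    second = {p.name: p.read_bytes() for p in emit_table_fixtures(tmp_path / "b")}
    assert first == second
    assert len(first) == 4
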