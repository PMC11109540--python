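"""Founder simulation, gene dropping, and pedigree relationship truth."""

import numpy as np
import pytest

from snperr import (
    GTClass,
    Pedigree,
    SyntheticCohortConfig,
    UNRELATED,
    build_benchmark_pedigree,
    gene_drop,
    read_vcf,
    simulate_founders,
    write_cohort_vcf,
)


class TestConfig:
    @pytest.mark.parametrize("maf", [(0.0, 0.5), (0.6, 0.6), (0.3, 0.1)])
    def test_invalid_maf_range_rejected(self, maf):
        with pytest.raises(ValueError, match="maf_range"):
            SyntheticCohortConfig(n_sites=10, maf_range=maf)

    def test_invalid_n_sites_rejected(self):
        with pytest.raises(ValueError, match="n_sites"):
            SyntheticCohortConfig(n_sites=0)


class TestFounders:
    def test_hwe_het_fraction_at_half(self):
        """At allele frequency pinned to 0.5 the heterozygote fraction is
        2f(1-f) = 0.5 within 3 binomial standard errors."""
        config = SyntheticCohortConfig(n_sites=100_000, maf_range=(0.5, 0.5), seed=4)
        genotypes, _ = simulate_founders(config, 1)
        g = genotypes["F1"]
        het = np.mean(g[:, 0] != g[:, 1])
        se = np.sqrt(0.5 * 0.5 / config.n_sites)
        assert abs(het - 0.5) < 3 * se

    def test_hwe_genotype_frequencies_follow_af(self):
        config = SyntheticCohortConfig(n_sites=200_000, maf_range=(0.05, 0.5), seed=8)
        genotypes, sites = simulate_founders(config, 1)
        dosage = genotypes["F1"].sum(axis=1)
        f = sites["af"].to_numpy()
        for target, expected in [(2, f**2), (1, 2 * f * (1 - f)), (0, (1 - f) ** 2)]:
            obs = np.mean(dosage == target)
            exp = expected.mean()
            assert abs(obs - exp) < 3 * np.sqrt(exp * (1 - exp) / config.n_sites)

    def test_zero_founders_gives_empty_matrix_valid_metadata(self):
        genotypes, sites = simulate_founders(SyntheticCohortConfig(n_sites=5, seed=0), 0)
        assert genotypes == {}
        assert len(sites) == 5 and set(sites.columns) >= {"chrom", "pos", "ref", "alt", "af"}
        assert (sites["ref"] != sites["alt"]).all()

    def test_seeded_determinism(self):
        config = SyntheticCohortConfig(n_sites=500, seed=123)
        a, sa = simulate_founders(config, 3)
        b, sb = simulate_founders(config, 3)
        assert all(np.array_equal(a[k], b[k]) for k in a)
        assert sa.equals(sb)


class TestGeneDrop:
    def trio(self):
        return Pedigree(
            members=["dad", "mom", "kid"],
            parents={"dad": None, "mom": None, "kid": ("dad", "mom")},
        )

    def test_mendelian_certainty_hom_parents(self):
        ped = self.trio()
        n = 200
        founders = {
            "dad": np.zeros((n, 2), dtype=np.int8),
            "mom": np.zeros((n, 2), dtype=np.int8),
        }
        kid = gene_drop(ped, founders, seed=0)["kid"]
        assert not kid.any()
        founders["mom"] = np.ones((n, 2), dtype=np.int8)
        kid = gene_drop(ped, founders, seed=0)["kid"]
        assert (kid.sum(axis=1) == 1).all()  # always 0/1

    def test_segregation_ratio_het_parents(self):
        """het × het segregates 1:2:1 within 3 standard errors."""
        ped = self.trio()
        n = 120_000
        het = np.tile(np.array([[0, 1]], dtype=np.int8), (n, 1))
        kid = gene_drop(ped, {"dad": het, "mom": het}, seed=9)["kid"]
        dosage = kid.sum(axis=1)
        for target, p in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            obs = np.mean(dosage == target)
            assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_offspring_alleles_come_from_parents(self):
        """Every transmitted allele is one of the parent's two alleles."""
        ped = build_benchmark_pedigree()
        config = SyntheticCohortConfig(n_sites=300, seed=2)
        founders, _ = simulate_founders(config, len(ped.founders), names=ped.founders)
        geno = gene_drop(ped, founders, seed=3)
        for member, pair in ped.parents.items():
            if pair is None:
                continue
            for slot, parent in enumerate(pair):
                child_allele = geno[member][:, slot]
                pg = geno[parent]
                assert ((child_allele == pg[:, 0]) | (child_allele == pg[:, 1])).all()

    def test_missing_founder_genotypes_fatal(self):
        ped = self.trio()
        with pytest.raises(ValueError, match="mom"):
            gene_drop(ped, {"dad": np.zeros((5, 2), dtype=np.int8)}, seed=0)

    def test_seeded_determinism_end_to_end(self):
        ped = build_benchmark_pedigree()
        config = SyntheticCohortConfig(n_sites=400, seed=6)
        founders, _ = simulate_founders(config, len(ped.founders), names=ped.founders)
        a = gene_drop(ped, founders, seed=7)
        b = gene_drop(ped, founders, seed=7)
        assert all(np.array_equal(a[k], b[k]) for k in a)


class TestBenchmarkPedigree:
    def test_degrees_relative_to_focal(self, benchmark_pedigree):
        ped = benchmark_pedigree
        expected = {
            "father": 1,
            "mother": 1,
            "sibling": 1,
            "gf": 2,
            "gm": 2,
            "uncle": 2,
            "half_sib": 2,
            "cousin": 3,
            "stepmother": UNRELATED,
            "aunt_in_law": UNRELATED,
            "unrel1": UNRELATED,
            "unrel2": UNRELATED,
        }
        for member, degree in expected.items():
            assert ped.degree("proband", member) == degree, member

    def test_expected_kinship_values(self, benchmark_pedigree):
        ped = benchmark_pedigree
        assert ped.kinship("proband", "proband") == 0.5
        assert ped.kinship("proband", "father") == 0.25
        assert ped.kinship("proband", "half_sib") == 0.125
        assert ped.kinship("proband", "cousin") == 0.0625
        assert ped.kinship("proband", "unrel1") == 0.0

    def test_truth_degree_map_is_symmetric_and_total(self, benchmark_pedigree):
        ped = benchmark_pedigree
        truth = ped.truth_degree
        n = len(ped.members)
        assert len(truth) == n * (n - 1) // 2
        for a in ped.members:
            for b in ped.members:
                assert ped.degree(a, b) == ped.degree(b, a)

    def test_unknown_parent_reference_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            Pedigree(members=["kid"], parents={"kid": ("ghost", "ghost2")})


class TestCohortVcf:
    def test_shape_and_round_trip(self, tmp_path):
        config = SyntheticCohortConfig(n_sites=3, seed=1)
        genotypes, sites = simulate_founders(config, 2)
        path = write_cohort_vcf(genotypes, sites, str(tmp_path / "c.vcf"))
        header, records = read_vcf(path)
        records = list(records)
        assert list(header.samples) == ["F1", "F2"]
        assert len(records) == 3
        for i, site in enumerate(records):
            assert site.pos == sites["pos"][i]
            for j, name in enumerate(["F1", "F2"]):
                assert site.calls[j].klass is not GTClass.OTHER
                assert sorted(site.calls[j].alleles) == sorted(genotypes[name][i])

    def test_af_info_emitted(self, tmp_path):
        config = SyntheticCohortConfig(n_sites=2, seed=1)
        genotypes, sites = simulate_founders(config, 1)
        path = write_cohort_vcf(genotypes, sites, str(tmp_path / "c.vcf"))
        _, records = read_vcf(path)
        for i, site in enumerate(records):
            assert site.raw.info["AF"][0] == pytest.approx(sites["af"][i], abs=1e-6)
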