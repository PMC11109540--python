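"""Shared fixtures: tiny handwritten VCFs and simulated cohorts."""

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from snperr import (
    SyntheticCohortConfig,
    build_benchmark_pedigree,
    gene_drop,
    simulate_founders,
    write_cohort_vcf,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##contig=<ID=2,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def make_vcf(path, rows, samples=("S1", "S2")):
    """Write a small plain-text VCF. Each row: (chrom, pos, ref, alt, gts)
    where gts is a list of GT strings (with optional :DP suffix)."""
    lines = [VCF_HEADER.format(samples="\t".join(samples))]
    for chrom, pos, ref, alt, gts in rows:
        fmt = "GT:DP" if ":" in gts[0] else "GT"
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\t{fmt}\t" + "\t".join(gts) + "\n"
        )
    path = str(path)
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path


@pytest.fixture
def toy_vcf(tmp_path):
    """3 sites × 2 samples covering het, hom-ref, hom-alt and phased calls."""
    rows = [
        ("1", 100, "A", "C", ["0/1", "0/0"]),
        ("1", 200, "G", "T", ["1|0", "1/1"]),
        ("2", 300, "T", "A", ["1/1", "./."]),
    ]
    return make_vcf(tmp_path / "toy.vcf", rows)


@pytest.fixture
def odd_vcf(tmp_path):
    """Edge cases: half-call, multiallelic genotype, haploid, phased missing."""
    rows = [
        ("1", 10, "A", "C", ["./1", "0/1"]),
        ("1", 20, "A", "C,G", ["1/2", "0/2"]),
        ("1", 30, "A", "C", ["1", "0/0"]),
        ("1", 40, "A", "C", [".|.", "1/1"]),
    ]
    return make_vcf(tmp_path / "odd.vcf", rows)


@pytest.fixture(scope="session")
def benchmark_pedigree():
    return build_benchmark_pedigree()


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, benchmark_pedigree):
    """Gene-dropped 12k-site cohort VCF for injection/kinship tests."""
    ped = benchmark_pedigree
    config = SyntheticCohortConfig(n_sites=12_000, seed=11)
    founders, sites = simulate_founders(config, len(ped.founders), names=ped.founders)
    genotypes = gene_drop(ped, founders, seed=12)
    path = tmp_path_factory.mktemp("cohort") / "cohort.vcf.gz"
    write_cohort_vcf(genotypes, sites, str(path))
    return {"path": str(path), "pedigree": ped, "genotypes": genotypes, "sites": sites}
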