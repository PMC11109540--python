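"""Synthetic cohorts: HWE founders, gene-dropped pedigrees, VCF export.

Desk-scale stand-in for array-masked population genotype panels and
pedigree simulators. Founder genotypes are drawn site-independently under
Hardy–Weinberg equilibrium with per-site alternate-allele frequencies
uniform over a configurable MAF window; offspring genotypes are produced by
gene dropping — at each site each parent transmits one of its two alleles
uniformly at random, independently across sites (no linkage, recombination
map, or crossover interference: the kinship estimator downstream uses only
per-site genotype-class counts, for which LD structure is irrelevant).

Relationship truth is derived from the pedigree itself via the standard
recursive kinship coefficient, so every pair's expected degree is exact
(φ = 2^-(d+1) for degree-d relatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .vcf_io import VcfError

__all__ = [
    "UNRELATED",
    "Pedigree",
    "SyntheticCohortConfig",
    "simulate_founders",
    "gene_drop",
    "build_benchmark_pedigree",
    "write_cohort_vcf",
]

#: Degree label for pairs sharing no pedigree ancestry (or beyond 3rd degree).
UNRELATED = "UN"

Degree = Union[int, str]


@dataclass
class Pedigree:
    """Founder/parent/offspring structure with derived relationship truth.

    ``parents`` maps each member to ``(father, mother)``; founders map to
    ``None``. Truth degrees come from the pedigree-expected kinship
    coefficient φ: degree d relatives have φ = 2^-(d+1); pairs with φ = 0
    (and anything beyond third degree) are UNRELATED.
    """

    members: List[str]
    parents: Dict[str, Optional[Tuple[str, str]]]

    def __post_init__(self) -> None:
        for m in self.members:
            pair = self.parents.get(m)
            if pair is not None:
                for p in pair:
                    if p not in self.parents:
                        raise ValueError(f"parent {p!r} of {m!r} is not a pedigree member")
        self._depth_cache: Dict[str, int] = {}
        self._kin_cache: Dict[Tuple[str, str], float] = {}

    @property
    def founders(self) -> List[str]:
        return [m for m in self.members if self.parents.get(m) is None]

    def _depth(self, m: str) -> int:
        if m in self._depth_cache:
            return self._depth_cache[m]
        pair = self.parents.get(m)
        d = 0 if pair is None else 1 + max(self._depth(p) for p in pair)
        self._depth_cache[m] = d
        return d

    def drop_order(self) -> List[str]:
        """Members ordered so every parent precedes its offspring."""
        return sorted(self.members, key=self._depth)

    def kinship(self, i: str, j: str) -> float:
        """Pedigree-expected kinship coefficient φ (recursive, founders
        assumed unrelated and non-inbred)."""
        if self._depth(i) < self._depth(j):
            i, j = j, i
        key = (i, j)
        if key in self._kin_cache:
            return self._kin_cache[key]
        if i == j:
            pair = self.parents.get(i)
            f = self.kinship(*pair) if pair is not None else 0.0
            phi = 0.5 * (1.0 + f)
        else:
            pair = self.parents.get(i)  # i is the deeper individual
            if pair is None:
                phi = 0.0
            else:
                phi = 0.5 * (self.kinship(pair[0], j) + self.kinship(pair[1], j))
        self._kin_cache[key] = phi
        return phi

    def degree(self, i: str, j: str) -> Degree:
        """Relationship degree of a pair: 0 for self/duplicate, 1–3, or
        UNRELATED beyond the third degree."""
        phi = self.kinship(i, j)
        if phi <= 0.0:
            return UNRELATED
        d = round(np.log2(1.0 / phi)) - 1
        return int(d) if 0 <= d <= 3 else UNRELATED

    @property
    def truth_degree(self) -> Dict[frozenset, Degree]:
        """Symmetric map over all unordered member pairs."""
        out: Dict[frozenset, Degree] = {}
        for a in self.members:
            for b in self.members:
                if a < b:
                    out[frozenset((a, b))] = self.degree(a, b)
        return out


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Size and allele-frequency window of a simulated cohort.

    ``maf_range`` bounds the per-site alternate-allele frequency, drawn
    uniformly; the default (0.05, 0.5) mimics a common-variant array panel
    and avoids near-monomorphic sites.
    """

    n_sites: int = 50_000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")


# distinct RNG seed domains: reusing one user seed across founder
# simulation, gene dropping and error injection must yield independent
# streams, never a replay of another step's uniforms
_FOUNDER_DOMAIN = 0xF00D
_DROP_DOMAIN = 0xD120

_REF_ALT = np.array(["A", "C", "G", "T"])


def simulate_founders(
    config: SyntheticCohortConfig, n_founders: int, names: Optional[Sequence[str]] = None
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Draw founder genotypes under site-independent Hardy–Weinberg.

    Returns ``(genotypes, sites)`` where ``genotypes`` maps founder name to
    an (n_sites, 2) int8 allele array and ``sites`` holds chrom/pos/ref/alt
    and the drawn alternate-allele frequency ``af`` per site.
    """
    rng = np.random.default_rng(np.random.SeedSequence((_FOUNDER_DOMAIN, config.seed)))
    n = config.n_sites
    af = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n + 1, dtype=np.int64) * 10,
            "ref": _REF_ALT[ref_idx],
            "alt": _REF_ALT[alt_idx],
            "af": af,
        }
    )
    if names is None:
        names = [f"F{i + 1}" for i in range(n_founders)]
    if len(names) != n_founders:
        raise ValueError("names length must equal n_founders")
    genotypes = {
        name: (rng.random(size=(n, 2)) < af[:, None]).astype(np.int8) for name in names
    }
    return genotypes, sites


def gene_drop(
    pedigree: Pedigree,
    founder_genotypes: Mapping[str, np.ndarray],
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Drop founder alleles through the pedigree, one Mendelian draw per
    transmitted allele per site.

    Returns allele arrays for every pedigree member, founders included.
    Raises if any founder lacks genotypes.
    """
    missing = [f for f in pedigree.founders if f not in founder_genotypes]
    if missing:
        raise ValueError(f"no genotypes supplied for founders: {', '.join(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence((_DROP_DOMAIN, seed)))
    genotypes: Dict[str, np.ndarray] = {}
    for member in pedigree.drop_order():
        pair = pedigree.parents.get(member)
        if pair is None:
            genotypes[member] = np.asarray(founder_genotypes[member], dtype=np.int8)
            continue
        n = genotypes[pair[0]].shape[0]
        rows = np.arange(n)
        picks = rng.integers(0, 2, size=(n, 2))
        child = np.empty((n, 2), dtype=np.int8)
        child[:, 0] = genotypes[pair[0]][rows, picks[:, 0]]
        child[:, 1] = genotypes[pair[1]][rows, picks[:, 1]]
        genotypes[member] = child
    return genotypes


def build_benchmark_pedigree() -> Pedigree:
    """The fixed three-generation pedigree used by the kinship benchmark.

    Relative to the focal individual ``proband`` it contains first-degree
    (both parents, a full sibling), second-degree (both paternal
    grandparents, a half-sibling, an uncle), and third-degree (a first
    cousin) relatives, plus married-in founders and two fully unrelated
    individuals.
    """
    parents: Dict[str, Optional[Tuple[str, str]]] = {
        # generation 0 founders
        "gf": None,
        "gm": None,
        "mother": None,
        "stepmother": None,
        "aunt_in_law": None,
        "unrel1": None,
        "unrel2": None,
        # generation 1
        "father": ("gf", "gm"),
        "uncle": ("gf", "gm"),
        # generation 2
        "proband": ("father", "mother"),
        "sibling": ("father", "mother"),
        "half_sib": ("father", "stepmother"),
        "cousin": ("uncle", "aunt_in_law"),
    }
    return Pedigree(members=list(parents), parents=parents)


def write_cohort_vcf(
    genotypes: Mapping[str, np.ndarray],
    sites: pd.DataFrame,
    path: str,
    with_af_info: bool = True,
) -> str:
    """Write a GT-only multi-sample VCF for a simulated cohort.

    Genotypes are emitted unphased; the drawn alternate-allele frequency is
    optionally carried as INFO/AF. Output is bgzipped when ``path`` ends in
    ``.gz``. Returns the path written.
    """
    samples = list(genotypes)
    header = pysam.VariantHeader()
    header.add_line("##source=snperr-synthetic-cohort")
    contigs = pd.unique(sites["chrom"].astype(str))
    max_pos = int(sites["pos"].max()) if len(sites) else 1
    for contig in contigs:
        header.add_line(f"##contig=<ID={contig},length={max_pos + 1000}>")
    if with_af_info:
        header.add_line(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Simulated alternate allele frequency">'
        )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)

    mats = [np.asarray(genotypes[s]) for s in samples]
    n_sites = len(sites)
    for s, mat in zip(samples, mats):
        if mat.shape != (n_sites, 2):
            raise ValueError(f"genotypes for {s!r} have shape {mat.shape}, expected ({n_sites}, 2)")

    mode = "wz" if str(path).endswith(".gz") else "w"
    try:
        out = pysam.VariantFile(str(path), mode, header=header)
    except (OSError, ValueError) as exc:
        raise VcfError(f"cannot write VCF {path!r}: {exc}") from exc
    with out:
        chroms = sites["chrom"].astype(str).to_numpy()
        poss = sites["pos"].to_numpy()
        refs = sites["ref"].astype(str).to_numpy()
        alts = sites["alt"].astype(str).to_numpy()
        afs = sites["af"].to_numpy() if "af" in sites and with_af_info else None
        for i in range(n_sites):
            rec = out.new_record(
                contig=chroms[i], start=int(poss[i]) - 1, alleles=(refs[i], alts[i])
            )
            if afs is not None:
                rec.info["AF"] = (float(afs[i]),)
            for j in range(len(samples)):
                rec.samples[j]["GT"] = (int(mats[j][i, 0]), int(mats[j][i, 1]))
            out.write(rec)
    return str(path)
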