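"""KING-robust kinship estimation and the error-sweep degradation benchmark.

The pairwise relatedness estimator is the between-family KING-robust
kinship coefficient, computed from per-site genotype-class counts over the
sites where both samples have a diploid biallelic call:

    φ̂ = (N_het,het − 2·N_opp) / (2·min(N_het,i, N_het,j))
         + 1/2 − (N_het,i + N_het,j) / (4·min(N_het,i, N_het,j))

where N_het,het counts sites at which both samples are heterozygous, N_opp
counts opposite-homozygote sites (one 0/0, the other 1/1), and N_het,i is
sample i's heterozygote count over the compared sites. Expected values are
0.5 for duplicates/MZ twins and 2^-(d+1) for degree-d relatives; unrelated
pairs scatter around 0 (negative estimates are possible and meaningful).

Degrees are inferred with the standard powers-of-two midpoint thresholds
2^-(d+3/2): φ̂ > 0.3536 → duplicate (degree 0), (0.1768, 0.3536] → 1st,
(0.0884, 0.1768] → 2nd, (0.0442, 0.0884] → 3rd, else unrelated.

The benchmark mirrors a kinship-robustness experiment: starting from an
error-free gene-dropped cohort, one error mode at a time is injected into a
single focal sample over a grid of rates, and degree-classification
accuracy over all pairs involving the focal sample is scored against the
pedigree truth.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .error_model import MODES, ErrorSpec
from .injector import inject
from .synthetic_data import (
    UNRELATED,
    Degree,
    Pedigree,
    SyntheticCohortConfig,
    build_benchmark_pedigree,
    gene_drop,
    simulate_founders,
    write_cohort_vcf,
)
from .vcf_io import GTClass, read_vcf

__all__ = [
    "PairCounts",
    "KinshipEstimate",
    "SweepResult",
    "KinshipError",
    "DEGREE_THRESHOLDS",
    "pair_counts",
    "king_robust_phi",
    "classify_degree",
    "load_dosages",
    "run_sweep",
    "run_benchmark",
]


class KinshipError(RuntimeError):
    """Kinship estimate undefined for the given counts."""


#: Lower φ̂ bound (exclusive) for each inferred degree, in decreasing order.
DEGREE_THRESHOLDS: Tuple[Tuple[float, Degree], ...] = (
    (2.0 ** -1.5, 0),
    (2.0 ** -2.5, 1),
    (2.0 ** -3.5, 2),
    (2.0 ** -4.5, 3),
)


@dataclass(frozen=True)
class PairCounts:
    """Shared genotype-class counts for one sample pair."""

    n_het_het: int
    n_opp_hom: int
    n_het_i: int
    n_het_j: int
    n_compared: int


@dataclass(frozen=True)
class KinshipEstimate:
    phi: float
    inferred_degree: Degree


def dosages_from_calls(calls: Sequence) -> np.ndarray:
    """Alternate-allele dosage vector from GenotypeCall objects; -1 marks
    missing or OTHER-class calls."""
    klass_to_dosage = {GTClass.HOM_REF: 0, GTClass.HET: 1, GTClass.HOM_ALT: 2}
    return np.array([klass_to_dosage.get(c.klass, -1) for c in calls], dtype=np.int8)


def load_dosages(vcf_path: str) -> Tuple[List[str], np.ndarray]:
    """Read a cohort VCF into a (samples × sites) dosage matrix.

    Dosage is the alternate-allele count 0/1/2; missing and OTHER-class
    calls are -1 and are excluded pairwise by :func:`pair_counts`.
    """
    header, records = read_vcf(vcf_path)
    samples = list(header.samples)
    klass_to_dosage = {GTClass.HOM_REF: 0, GTClass.HET: 1, GTClass.HOM_ALT: 2}
    cols = []
    for site in records:
        cols.append([klass_to_dosage.get(c.klass, -1) for c in site.calls])
    if not cols:
        return samples, np.empty((len(samples), 0), dtype=np.int8)
    return samples, np.asarray(cols, dtype=np.int8).T


def pair_counts(
    dosages_i: np.ndarray, dosages_j: np.ndarray
) -> PairCounts:
    """Tally the KING-robust input counts for one pair of dosage vectors.

    Sites where either vector is negative (missing/OTHER) are excluded from
    every count.
    """
    gi = np.asarray(dosages_i)
    gj = np.asarray(dosages_j)
    if gi.shape != gj.shape:
        raise ValueError(f"dosage length mismatch: {gi.shape} vs {gj.shape}")
    ok = (gi >= 0) & (gj >= 0)
    gi, gj = gi[ok], gj[ok]
    return PairCounts(
        n_het_het=int(np.count_nonzero((gi == 1) & (gj == 1))),
        n_opp_hom=int(np.count_nonzero(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0)))),
        n_het_i=int(np.count_nonzero(gi == 1)),
        n_het_j=int(np.count_nonzero(gj == 1)),
        n_compared=int(gi.size),
    )


def king_robust_phi(counts: PairCounts) -> float:
    """Between-family KING-robust kinship coefficient φ̂."""
    m = min(counts.n_het_i, counts.n_het_j)
    if m == 0:
        raise KinshipError(
            "KING-robust kinship undefined: a sample has no heterozygous calls over the compared sites"
        )
    return (
        (counts.n_het_het - 2.0 * counts.n_opp_hom) / (2.0 * m)
        + 0.5
        - (counts.n_het_i + counts.n_het_j) / (4.0 * m)
    )


def classify_degree(phi: float) -> Degree:
    """Map φ̂ to an inferred relationship degree via the standard
    powers-of-two midpoint thresholds; beyond 3rd degree is UNRELATED."""
    for lower, degree in DEGREE_THRESHOLDS:
        if phi > lower:
            return degree
    return UNRELATED


def estimate(dosages_i: np.ndarray, dosages_j: np.ndarray) -> KinshipEstimate:
    phi = king_robust_phi(pair_counts(dosages_i, dosages_j))
    return KinshipEstimate(phi=phi, inferred_degree=classify_degree(phi))


@dataclass
class SweepResult:
    """Degree-classification accuracy along one mode's error-rate grid."""

    mode: str
    rate_grid: List[float]
    accuracy: List[float]
    guessing_floor: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": self.mode,
                "rate": self.rate_grid,
                "accuracy": self.accuracy,
                "guessing_floor": self.guessing_floor,
            }
        )


def _score_focal_pairs(
    samples: List[str],
    dosages: np.ndarray,
    focal: str,
    pedigree: Pedigree,
) -> float:
    """Fraction of (focal, other) pairs whose inferred degree matches the
    pedigree truth."""
    fi = samples.index(focal)
    correct = 0
    total = 0
    for j, other in enumerate(samples):
        if other == focal:
            continue
        est = estimate(dosages[fi], dosages[j])
        truth = pedigree.degree(focal, other)
        correct += est.inferred_degree == truth
        total += 1
    if total == 0:
        raise KinshipError("no pairs to score: cohort has only the focal sample")
    return correct / total


def guessing_floor(pedigree: Pedigree, focal: str, samples: Sequence[str]) -> float:
    """Accuracy of always predicting the most common truth degree among the
    scored pairs — the floor any informative classifier must beat."""
    truths = [pedigree.degree(focal, s) for s in samples if s != focal]
    if not truths:
        raise KinshipError("no pairs to score")
    top = max(set(truths), key=truths.count)
    return truths.count(top) / len(truths)


def run_sweep(
    cohort_vcf: str,
    focal: str,
    pedigree: Pedigree,
    mode: str,
    rate_grid: Sequence[float],
    seed: int = 0,
    workdir: Optional[str] = None,
) -> SweepResult:
    """Inject one error mode into the focal sample over a rate grid and
    score degree-inference accuracy at each rate.

    Every rate starts from the clean cohort (errors are not cumulative) and
    all other modes stay at 0. Injection seeds are derived deterministically
    from ``seed`` and the grid index.
    """
    if mode not in MODES:
        raise ValueError(f"unknown error mode {mode!r}")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(rate_grid)) % (2**31)
    accuracies: List[float] = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for k, rate in enumerate(rate_grid):
            out = str(Path(tmp) / f"{mode}_{k}.vcf.gz")
            inject(
                cohort_vcf,
                focal,
                ErrorSpec.single_mode(mode, float(rate)),
                seed=int(child_seeds[k]),
                output_vcf=out,
            )
            samples, dosages = load_dosages(out)
            accuracies.append(_score_focal_pairs(samples, dosages, focal, pedigree))
    header, _ = read_vcf(cohort_vcf)
    return SweepResult(
        mode=mode,
        rate_grid=[float(r) for r in rate_grid],
        accuracy=accuracies,
        guessing_floor=guessing_floor(pedigree, focal, list(header.samples)),
    )


def run_benchmark(
    n_sites: int = 50_000,
    seed: int = 0,
    modes: Sequence[str] = MODES,
    rate_max: float = 0.20,
    rate_step: float = 0.01,
    focal: str = "proband",
    workdir: Optional[str] = None,
) -> pd.DataFrame:
    """End-to-end degradation benchmark on the built-in pedigree.

    Simulates HWE founders, gene-drops the benchmark pedigree, writes the
    cohort VCF, then sweeps each requested mode from 0 to ``rate_max`` in
    ``rate_step`` increments (grid always includes 0). Returns a tidy frame
    with columns mode, rate, accuracy, guessing_floor.
    """
    pedigree = build_benchmark_pedigree()
    config = SyntheticCohortConfig(n_sites=n_sites, seed=seed)
    founder_geno, sites = simulate_founders(
        config, n_founders=len(pedigree.founders), names=pedigree.founders
    )
    genotypes = gene_drop(pedigree, founder_geno, seed=seed + 1)
    n_steps = int(round(rate_max / rate_step))
    rate_grid = [round(k * rate_step, 10) for k in range(n_steps + 1)]
    frames = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        cohort = str(Path(tmp) / "cohort.vcf.gz")
        write_cohort_vcf(genotypes, sites, cohort)
        for i, mode in enumerate(modes):
            result = run_sweep(
                cohort, focal, pedigree, mode, rate_grid, seed=seed + 1000 + i, workdir=workdir
            )
            frames.append(result.to_frame())
    return pd.concat(frames, ignore_index=True)
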