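# Methods

## Error model

The simulator treats each diploid biallelic genotype of one designated
sample as a categorical random variable over its class's possible
miscalls. Nine directed transition modes cover every ordered pair of
source class ∈ {het, hom-ref, hom-alt} and target class ∈ {hom-ref, het,
hom-alt, missing} \ {source}: `rarr`, `raaa`, `ramm` act on heterozygotes,
`rrra`, `rraa`, `rrmm` on hom-ref, and `aara`, `aarr`, `aamm` on hom-alt.
Missing genotypes are a sink — no mode converts `./.` back to a call — and
calls outside the diploid biallelic alphabet (half-calls, allele index
> 1, ploidy ≠ 2) are carried through untouched, because the model is
defined only over the four biallelic diploid states.

Per eligible genotype the injector makes **one** categorical draw over
{applicable modes} ∪ {stay}, with the stay mass the complement of the
class's mode-probability sum. This makes the three per-class sums ≤ 1 a
hard validity constraint; specifications violating it are rejected at
validation, not renormalized, because silent renormalization would make
the realized rates disagree with what the user asked for. Mutated
genotypes are written as the canonical unphased representative of the
target class (`0/0`, `0/1`, `1/1`, `./.`); genotypes the draw leaves
alone are preserved byte-wise, including phase separators and allele
order. Only the GT subfield is ever rewritten; all other FORMAT
subfields, and INFO (including AC/AF, which become stale by design), pass
through unchanged.

### Randomness

A single PCG64 stream drives all draws, one per eligible genotype in file
order, so (input, spec, seed) fully determines the output. Each module
that consumes randomness — founder simulation, gene dropping, injection —
seeds its stream through a module-specific `SeedSequence` salt. This
matters: seeding two different steps of a pipeline with the same small
integer would otherwise replay one step's uniform stream inside another,
and because the founder generator's first draws are the per-site allele
frequencies (which the heterozygosity of every downstream sample tracks),
an unsalted injector stream is *correlated with which sites are
heterozygous* and realizes biased error rates. Unseeded runs draw an
entropy seed and record it in the injection report.

## Concordance and NRC

The evaluator streams truth and query VCFs in lockstep (both must be
sorted identically; contigs ranked by header order, then first
appearance) and matches records by exact (chrom, pos, ref, alts). It
keys every comparison on the **truth** class: e_ra counts truth-het sites
where the query differs, whatever the query class is. Beyond the six e/m
counts it keeps the full 4×4 truth×query transition matrix over
{hom-ref, het, hom-alt, missing}, whose off-diagonal cells are exactly
the injector's per-mode change counters when run on an (input, injected)
pair — the closure used throughout the test suite as its oracle.

Non-reference concordance is

    NRC = 1 − (e_rr + e_ra + e_aa) / (e_rr + e_ra + e_aa + m_ra + m_aa)

with m_rr excluded so that the large trivially concordant hom-ref mass
cannot mask real discordance. When the denominator is zero the score is
undefined and reported as an error rather than a default value.

Missing handling is a genuine convention choice in concordance tooling:
by default a site missing on either side contributes to the matrix's
missing row/column and to `excluded` but not to e/m (so missingness does
not count against NRC); `missing_as_mismatch=True` instead counts a
query-missing call at a truth-called site as a mismatch of the truth
class. Both policies are implemented; exclusion is the default.

## Synthetic cohorts

Founder genotypes are drawn under site-independent Hardy–Weinberg
equilibrium: per-site alternate-allele frequency f ~ Uniform(maf_range),
each allele Bernoulli(f). The default window (0.05, 0.5) mimics a
common-variant array panel and keeps sites polymorphic. Offspring are
gene-dropped: at each site each parent transmits one of its two alleles
uniformly at random, independently across sites.

Sites are deliberately **unlinked** — no genetic map, recombination, or
crossover interference. The KING-robust estimator uses only marginal
per-site genotype-class counts, whose expectations depend on kinship but
not on LD; linkage would only correlate site contributions and inflate
the estimator's variance bookkeeping without changing any expectation
tested here. Consequently the synthetic data says nothing about
IBD-segment methods, and passing tests demonstrate correctness of the
estimator arithmetic and the error model's effect on it, not performance
on real LD-structured genomes. Other absent features of real data:
population structure, genotyping batch effects, allele-frequency
misspecification, and the real MAF spectrum (real arrays are skewed
toward common variants differently than a uniform window).

The built-in benchmark pedigree spans three generations around a focal
`proband`: parents and a full sibling (1st degree), paternal grandparents,
an uncle and a half-sibling (2nd), a first cousin (3rd), and four
married-in/unrelated founders. Truth degrees are not hand-tabulated but
derived from the pedigree-expected kinship coefficient via the standard
recursion (φ(i,i) = (1+F)/2, φ(i,j) = ½[φ(father_i, j) + φ(mother_i, j)]
expanding the deeper individual), then binned by φ = 2^−(d+1); this keeps
truth and topology consistent by construction.

## Kinship estimation and the sweep

The estimator is the between-family KING-robust coefficient (the variant
implemented by akt and plink2):

    φ̂ = (N_het,het − 2·N_opp) / (2·min(N_i, N_j)) + 1/2 − (N_i + N_j) / (4·min(N_i, N_j))

over sites where both samples have diploid biallelic calls; N_i is sample
i's heterozygote count on those sites. φ̂ of an exact duplicate is 0.5
identically. Degrees use the standard midpoint thresholds 2^−(d+3/2):
(0.3536, ∞) → 0, (0.1768, 0.3536] → 1, (0.0884, 0.1768] → 2,
(0.0442, 0.0884] → 3, else unrelated; upper boundaries resolve to the
more-related bin.

The sweep holds all modes but one at zero, injects the chosen mode into
the focal sample at each grid rate **starting fresh from the clean
cohort** (rates are levels, not increments), and scores the fraction of
(focal, other) pairs whose inferred degree equals pedigree truth. The
reported guessing floor is the accuracy of always predicting the modal
truth degree among scored pairs (4/12 for the built-in pedigree, where
2nd-degree and unrelated tie).

## Problem sizes and numerical choices

- Benchmark default: 50,000 sites, 13 individuals. At this scale the
  binomial noise on φ̂ (s.d. ≲ 0.01) is far from the 0.018–0.073 gaps to
  the nearest degree thresholds, so clean-data classification is exact.
- Test-suite cohorts use 12,000 sites — the smallest scale at which
  baseline classification stays clean across seeds (at 6,000 sites the
  borderline 3rd-degree pair already misclassifies on clean data) — and
  rate-recovery checks use ≥ 100,000 heterozygous genotypes with
  3-binomial-standard-error acceptance bands.
- Statistical assertions are all ±3σ under the relevant binomial law,
  with fixed seeds; exact assertions (non-target invariance, report/
  concordance closure, duplicate φ̂ = 0.5) use equality.
- Degenerate inputs: empty record streams write valid header-only VCFs;
  zero founders yield an empty matrix with valid site metadata; NRC and
  φ̂ raise on undefined denominators instead of returning NaN.

## Known limitations

- hom-alt → hom-ref swaps (`aarr`) barely move φ̂ in HWE cohorts with
  alternate-allele frequency ≤ 0.5: hom-alt is the rarest class, and each
  flip creates an opposite-homozygote only when the partner is hom-alt
  while destroying one when the partner is hom-ref, so the net shift
  stays well below the distance to any degree threshold even at a 20%
  rate. The mirrored mode `rraa` is the destructive one (it acts on the
  most abundant class and almost always creates opposite-homozygotes),
  collapsing accuracy to the unrelated-guessing level at high rates.
- INFO AC/AF are not recomputed after injection; downstream tools that
  trust them will see stale values.
- The concordance evaluator compares one sample at a time and requires
  identically sorted inputs; it does not re-sort or index.
- BCF, CRAM, structural variants and multiallelic *error simulation* are
  out of scope (multiallelic records pass through unmodified).
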