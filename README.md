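# snperr

Probabilistic simulation of SNP genotyping error and missingness in VCF
files — plus the machinery to measure what that error does downstream.

Genotyping error arises at platform-specific rates and in
platform-specific *shapes*: low-pass sequencing plus imputation, FFPE
tissue, ancient DNA and forensic samples all miscall genotypes differently
(heterozygote drop-out looks nothing like reference/alternate swaps).
`snperr` lets you inject precisely specified error into **one chosen
sample** of a multi-sample VCF, leaving every other sample untouched, so
you can ask how a downstream analysis — kinship inference, GWAS, polygenic
scoring — degrades under each kind of error.

The package has three parts:

1. **Injector** — nine directed genotype-class transition modes, each with
   its own probability. A mode's name encodes source and target:
   `rarr` = het → hom-ref (0/1 or 1/0 → 0/0), `raaa` = het → hom-alt,
   `ramm` = het → missing, `rrra` = hom-ref → het, `rraa` = hom-ref →
   hom-alt, `rrmm` = hom-ref → missing, `aara` = hom-alt → het, `aarr` =
   hom-alt → hom-ref, `aamm` = hom-alt → missing. Each eligible genotype
   gets a single weighted categorical draw over its class's outcomes
   (the three applicable modes plus stay-unchanged), so per-class
   probabilities must sum to ≤ 1.
2. **Concordance evaluator** — per-class match/mismatch counts between a
   truth and a query VCF for one sample, the full truth×query transition
   matrix, and non-reference concordance

   NRC = 1 − (e_rr + e_ra + e_aa) / (e_rr + e_ra + e_aa + m_ra + m_aa)

   where e_\* are mismatch counts keyed on the truth class and m_ra, m_aa
   are het / hom-alt matches; hom-ref matches are deliberately excluded so
   abundant trivially concordant sites cannot inflate the score.
3. **Kinship benchmark** — a synthetic-cohort generator (Hardy–Weinberg
   founders, Mendelian gene-dropping through a built-in three-generation
   pedigree) and the between-family KING-robust kinship estimator

   φ̂ = (N_het,het − 2·N_opp) / (2·min(N_het,i, N_het,j)) + 1/2 −
       (N_het,i + N_het,j) / (4·min(N_het,i, N_het,j))

   with degree classification at the standard 2^−(d+3/2) thresholds, used
   to sweep each error mode from 0 to 20% and score degree-inference
   accuracy against pedigree truth.

## Worked example

Simulate a 12-member pedigree cohort, corrupt the proband, and measure the
damage:

```sh
snperr simulate --sites 50000 --seed 7 --output_vcf cohort.vcf.gz
snperr inject cohort.vcf.gz --sample proband --p_rarr 0.05 --p_raaa 0.01 \
    --seed 7 --output_vcf cohort.err.vcf.gz --report report.tsv
snperr concord -s proband cohort.vcf.gz cohort.err.vcf.gz
```

The injection report (`report.tsv`) counts what happened:

```
sample	proband
seed	7
sites_scanned	50000
eligible_hom_ref	27353
eligible_het	18032
eligible_hom_alt	4615
passthrough_other	0
changes_rarr	898
changes_raaa	158
...
```

898 / 18032 = 4.98% of the proband's heterozygous genotypes became 0/0 and
158 / 18032 = 0.88% became 1/1 — matching the configured 5% and 1% within
binomial noise. The concordance table confirms the same counts
independently (its het→hom-ref and het→hom-alt matrix cells equal the
report's counters exactly) and prints `NRC 0.953371`: 1 − 1056 mismatches
/ (1056 + 21,591 non-reference matches). All other samples are
byte-identical between the two files.

The same loop at benchmark scale:

```sh
snperr benchmark --sites 50000 --seed 7 --modes rraa,rarr --out sweep.tsv
```

writes a tidy table (mode, rate, accuracy, guessing_floor) of
degree-classification accuracy for all pairs involving the proband as each
mode's rate sweeps 0–20%; hom-ref→hom-alt swaps (`rraa`) collapse accuracy
toward the guessing floor while heterozygote drop-out (`rarr`) barely
moves it.

The same operations are available as library calls (`snperr.inject`,
`snperr.tally`, `snperr.nrc`, `snperr.run_benchmark`, ...).

## Scope notes

- Only the GT subfield of the target sample is ever rewritten; INFO AC/AF
  are **not** recomputed after injection.
- Half-calls, multiallelic genotypes and non-diploid calls pass through
  untouched (the error model is defined over diploid biallelic states).
- Missing genotypes are a sink: no mode converts `./.` back to a call.
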