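# strseqdb

Sequence-based short-tandem-repeat (STR) genotyping for forensic DNA
databasing.

Forensic DNA databases store length-based STR genotypes produced by capillary
electrophoresis (CE): each allele is a repeat number inferred from amplicon
size (e.g. `15`, or the micro-variant `9.3` = nine full repeats plus three
bases). Massively parallel sequencing (MPS) types the same loci by sequence,
which resolves *isometric alleles* (identical length, different internal
sequence) and exposes flanking insertions/deletions that make the CE-apparent
length disagree with the repeat count. A databasing laboratory adopting MPS
therefore needs to (a) call alleles from read counts under defensible
thresholds, (b) recalculate CE-compatible "pseudo-CE" designations so new
profiles remain searchable against legacy databases, and (c) quantify
concordance, QC behaviour and the population-genetic gain of sequence-level
typing. `strseqdb` implements that evaluation pipeline for a 23-marker panel
(22 autosomal STRs + amelogenin), together with a synthetic paired MPS/CE
cohort generator for testing it end to end.

## What it computes

**Allele calling.** Sequences below the analytical threshold (AT, default 50
reads) are discarded; candidate alleles are called above the interpretation
threshold (IT): 500 reads for homozygous, 100 for heterozygous genotypes. A
single candidate between the two IT values is flagged `possible_dropout`
rather than forced to a homozygote. Length-based stutter resolution removes
sequences one repeat unit below a parent with a read ratio ≤ 0.35.

**Designation arithmetic.** For an allele with repeat-count designation
*n.b* at a locus of period *p* carrying catalogued flanking indels with net
base shift Δ, the pseudo-CE designation re-expresses the apparent length

```
L = n·p + b + Δ   →   (L div p).(L mod p)
```

so a one-base 3′ deletion turns a 10-repeat D2S441 allele into CE `9.3`, a
two-base 5′ deletion turns D19S433 `15` into `14.2`, and a 13-base deletion
turns a five-repeat Penta D allele into `2.2`. Catalogue entries may carry an
explicit designation override where a locus convention departs from uniform
arithmetic.

**QC metrics.** Relative marker performance (per-marker read share; expected
value 100/23 = 4.35% under equal performance, with a well-balanced band of
mean ± 1 SD of marker means), heterozygote balance HB = minor/major reads
(flagged at ≤ 0.30), and univariate *n−1* stutter ratios summarised per locus
and per read-depth category (category I ≤ 63,500 total reads, category II
≥ 199,000).

**Concordance.** CE genotypes versus pseudo-CE designations recalculated from
sequence calls, with every disagreement classified (drop-out of the longer or
shorter allele, drop-in, other); allele- and locus-level percentages.

**Population genetics.** Allele frequencies, observed/unbiased expected
heterozygosity, matching probability MP = Σ g² over genotype classes, power
of discrimination PD = 1 − MP, power of exclusion PE = h²(1 − 2hH²), typical
paternity index TPI = 1/(2H), and an exact Hardy–Weinberg test conditional on
allele counts (full enumeration for small tables, seeded Monte-Carlo
permutation otherwise).

## Worked example

```python
from strseqdb import (default_config, generate_population, simulate_reads,
                      derive_ce_dataset, PipelineConfig, run_pipeline)

cfg = default_config(n_samples=50, seed=7)
genotypes = generate_population(cfg)
profiles = simulate_reads(genotypes, cfg)
ce = derive_ce_dataset(genotypes)

bundle = run_pipeline(PipelineConfig(seed=7, n_perm=5000), profiles=profiles,
                      ce_table=ce, write=False)
s = bundle["summary"]
print(f"allele concordance: {s['allele_concordance_pct']}%")
print(f"locus concordance:  {s['locus_concordance_pct']}%")
print(f"HB-flagged calls:   {s['n_hb_flagged']} of {s['n_calls']}")
pop = bundle["popgen"].set_index("locus")
print(pop.loc[["D12S391", "TH01", "D22S1045"],
              ["n", "h_obs", "h_exp", "pd", "tpi", "hwe_p"]].round(3))
```

prints

```
allele concordance: 100.0%
locus concordance:  100.0%
HB-flagged calls:   0 of 1100
           n  h_obs  h_exp     pd    tpi  hwe_p
locus
D12S391   50   0.80   0.82  0.924  2.500  0.441
TH01      50   0.86   0.78  0.894  3.571  0.251
D22S1045  50   0.74   0.77  0.887  1.923  0.427
```

With no injected drop-out/drop-in events the recalculated pseudo-CE profiles
reproduce the derived CE dataset exactly (100% at both levels); no
heterozygote falls below the 0.30 balance flag in this cohort; and the
per-locus statistics behave as expected for spectra drawn under
Hardy–Weinberg proportions (all exact-test p-values well above 0.05). The
trinucleotide locus D22S1045 shows the highest mean stutter ratio of the
panel (≈ 0.14 in this cohort versus ≈ 0.04 at TH01), reflecting its
configured slippage model.

The same stages are available from the shell:

```sh
strseqdb simulate --n-samples 50 --seed 7 --out-dir sim
strseqdb run --readcounts sim/readcounts.tsv --ce sim/ce_genotypes.tsv --seed 7
strseqdb concordance --ce sim/ce_genotypes.tsv --mps sim/readcounts.tsv
strseqdb popgen --ce sim/ce_genotypes.tsv
```

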