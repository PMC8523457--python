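# Methods

## Scope and model

`strseqdb` models the evaluation of sequence-based (MPS) STR typing against
length-based (CE) typing for a forensic reference-sample panel of 22
autosomal STRs plus amelogenin. The unit of data is a per-sample, per-locus
map from sequence alleles to integer read counts; everything downstream —
thresholded genotype calling, CE-compatible designation, QC statistics,
concordance classification and population-genetic parameters — is a
deterministic function of those counts and the locus/variant catalogue.

## Catalogue

Each locus records its repeat period (3 for D22S1045, 5 for Penta D/E, 4
otherwise), canonical motif and a repeat-region template of ordered blocks
flagged counted/uncounted toward the designation. Amelogenin is a panel
member but not an STR; it carries no repeat template and is excluded from
designation and stutter logic while still contributing to marker-share QC.

Variant entries record a dbSNP-style id, kind (SNP/insertion/deletion),
region relative to the repeat, and the signed net base change of the
bracketed indel description. Two refinements:

* `designation_shift` — the portion of the length change falling outside
  counted repeat sequence. For pure flanking indels it equals the net change
  (the default). For the D19S433 repeat-boundary deletion, two bases are
  deleted but repeat-unit counting already absorbs one of them (the carrier
  counts 12 units plus a 3-base partial), so only −1 enters the CE
  arithmetic: repeat-count `12.3` maps to CE `12.2`. Both designations are
  reported side by side, since catalogue conventions for these micro-variants
  are not harmonised.
* `ce_designation_override` — an explicit designation that supersedes
  arithmetic. The shipped Penta D [A/-] 3′ deletion entry records the
  observed CE `13.3` for the 14-repeat carrier although uniform arithmetic
  would give `13.4`; the locus-specific convention behind the observed
  mapping is not documented, so it is recorded rather than derived.

## Designation arithmetic

Repeat-unit counting sums the counted blocks and keeps leftover counted bases
as the partial (`n.b`, 0 < b < period). The pseudo-CE designation
re-expresses `L = n·p + b + Σ shift` in repeat units, erroring if a deletion
exceeds the allele length. The arithmetic conserves total bases (re-deriving
`L` from the output is the identity) and is the identity for SNP-only variant
lists. Designation equality is string-exact after normalisation; no size
tolerance is applied (CE sizing noise is out of scope).

## Calling

* AT retention is inclusive (reads ≥ 50 survive). The threshold's strictness
  at the boundary is a convention fixed here and exposed as a parameter.
* Stutter-vs-candidate resolution precedes calling: a sequence exactly one
  full unit below an occupied length class, with a read ratio to that class
  of ≤ 0.35, is classed as stutter. The ratio is computed against the summed
  reads of the parent *length class* so that isometric heterozygote parents
  (which share one stutter class) are handled correctly. The 0.35 bound sits
  above realistic stutter (≤ ~0.29 in the modelled ranges) and below
  realistic heterozygote balance; it is a package choice, exposed as a
  parameter.
* A single candidate in [IT_het, IT_hom) = [100, 500) is a no-call flagged
  `possible_dropout`, never a forced homozygote — silent conversion of allele
  drop-out into homozygosity is the failure mode this prevents. More than two
  candidates above IT_het yields a tri-allelic flag and no call.
* Homozygotes are represented as one allele plus a flag; they are expanded to
  two copies only where allele counting requires it (concordance matching,
  frequency estimation).

Run-level QC classifies cluster density against the 1,000–1,200 K/mm²
recommendation (closed optimal interval) and passes Q30 strictly above 75%.
Q30 summaries use the n−1 sample SD and are reported to one decimal;
percentages elsewhere to two decimals. Reported roundings are half-up, not
banker's.

## QC statistics

Relative marker performance divides each marker's reads by the profile total
(all 23 markers); the well-balanced band is the grand mean of marker means
± one SD of the marker means, flagging strictly outside the closed band.
Heterozygote balance is min/max of the two allelic read counts, flagged at
≤ 0.30. Stutter ratios are univariate ("defined by length"): stutter reads at
the n−1 length class divided by parent-class reads, skipped when the stutter
position coincides with the genotype's other allele (the reads would be
confounded). Read-depth categories use inclusive bounds (I: ≤ 63,500;
II: ≥ 199,000 total reads). Per locus × category summaries report n, mean,
n−1 SD (missing for single observations), median, min, max, and the count of
ratios strictly above 0.20.

## Concordance

Designation multisets are compared per sample × locus with both sides
expanded to two copies. Drop-out requires every surviving sequence
designation to lie within the CE support with exactly one CE allele
unmatched; direction (longer/shorter) follows designation value (full units,
then partial bases), not amplicon size. An empty CE set against a non-empty
sequence set is a drop-in (negative-control case); a locus with no sequence
call at all counts as one discordant locus and two unmatched alleles. Allele
concordance is matched designations over 2 × loci compared; locus concordance
is the fully-concordant fraction. Allele concordance can never fall below
locus concordance (a discordant locus loses at most two allele matches and
always loses its locus match).

## Population genetics

Formulas are the standard forensic definitions, each validated in the test
suite against a brute-force oracle:

* h_obs — heterozygote fraction of complete genotypes (incomplete genotypes
  are excluded per locus, not per sample);
* h_exp — unbiased Nei estimator `(2N/(2N−1))(1 − Σ p²)`; the choice of the
  bias-corrected form is an assumption of this package;
* MP — Σ of squared *observed* genotype-class frequencies (not
  expected-under-HWE), PD = 1 − MP exactly;
* PE = h²(1 − 2hH²), TPI = 1/(2H) with H = 1 − h_obs; TPI is reported
  infinite when no homozygote is observed.

The exact Hardy–Weinberg test conditions on allele counts: the p-value is the
probability mass of genotype tables whose conditional probability
`N!·Πm_i!·2^h / ((2N)!·Πn_ij!)` does not exceed the observed table's. Small
problems (≤ 4 alleles, N ≤ 50, bounded table space) are fully enumerated;
larger ones fall back to Monte-Carlo permutation of the allele vector
(default 10⁴–10⁵ permutations, vectorised, seed mandatory). Monomorphic loci
return p = 1 by convention. Ties in table probability are included on the
observed side with a 10⁻⁹ log-space tolerance.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with all
randomness derived from one seed:

* genotypes i.i.d. per locus under Hardy–Weinberg proportions from declared
  allele spectra (length designation plus isometric splits and catalogued
  variant carriers);
* per-sample total reads log-normal (default median 120k, log-SD 0.5 —
  spanning both read-depth categories);
* equal expected marker shares (the equal-performance expectation for a
  23-marker panel);
* heterozygote balance Beta(25, 5) (mean ≈ 0.83), applied as minor share
  HB/(1+HB) with a fair seeded coin deciding which allele is minor;
* stutter only at n−1, mean = intercept + slope·(repeat units) with Gaussian
  noise (SD 0.02), truncated at zero; micro-variant parents are reduced by a
  0.75 factor, encoding the observation that intermediate alleles stutter
  less than integer alleles; defaults put cohort means in the 10–15% range
  with the trinucleotide locus D22S1045 highest. A configured mean ≥ 1 is a
  model-misconfiguration error;
* read counts rounded to nearest integer (ties to even) so thresholding is
  exact; profile totals are sums of emitted reads by construction;
* explicit drop-out events zero an allele before stutter forms; drop-in
  events add a spurious sequence with specified reads.

Default spectra are plausible European-style frequency sets declared as
assumptions, including isometric splits at thirteen loci and common
micro-variant alleles (TH01 9.3, D1S1656 17.3, D21S11 x.2); they are not
estimates from any particular dataset. What the generator deliberately does
not model: per-base sequencing error, n+1/n−2 stutter, PCR inhibition,
degradation, and mixtures. Passing tests therefore demonstrate the
correctness of the analysis logic under the declared statistical structure,
not performance on real sequencing artefacts.

Four deterministic scenario builders reproduce worked-example cohort
structures exactly: a 247-sample × 22-locus paired cohort with exactly two
injected single-allele drop-outs (longer-allele at D2S1338, shorter at
Penta E, depth high enough that nothing else approaches the thresholds);
1,075 length-homozygous genotypes of which 181 are isometric heterozygotes
across thirteen loci; 5,434 heterozygous calls with exactly seven at
HB ≤ 0.30 (five at D2S1338, one each at D19S433 and D21S11); and 494 D19S433
alleles with 55 repeat-boundary-deletion carriers.

## Problem sizes and numerical choices

The test suite simulates cohorts of 25–250 samples for end-to-end checks and
2,500–3,200 samples × 1–3 loci for parameter-recovery checks (≥ 5,000 parent
alleles per stutter-recovery assertion, ±0.01 tolerance; frequency recovery
within three binomial SEs). HWE permutation-vs-enumeration agreement is
asserted within three Monte-Carlo SEs at 2×10⁴ permutations. Report files are
written with fixed decimal formatting, Unix newlines and sorted keys, so a
fixed configuration yields byte-identical bundles.

## Known limitations

Flanking variants are modelled through the catalogue, not through per-base
sequence strings; only the structures the shipped examples need are encoded.
The stutter filter's 0.35 bound cannot separate a genuine allele whose
balance falls below it from a pathological stutter above it — real casework
would adjudicate such calls manually. No substructure (θ) correction is
applied to the forensic parameters, and kinship statistics beyond TPI are out
of scope, as are Y-STRs and SE33 (absent from the modelled panel).
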