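# Methods

## Repeat detection

A microsatellite locus is a *maximal perfect tract*: `k ≥ min_units`
whole copies of a primitive 2–4 bp motif that cannot be extended by a
further full copy on either side. Detection compares each base with the
base one period downstream; a maximal stretch of equalities of period `p`
is one candidate tract, anchored at the position where the periodicity
begins, with `k = ⌊run length / p⌋` (partial trailing copies are never
counted). A tract whose motif is itself periodic (e.g. `ATAT`) is
reported only at the smaller period, so the same repeat is never counted
at two periods, and the motif is normalised to the lexicographically
minimal rotation of its cycle class so `(CA)n` and `(AC)n` name one
locus. Non-ACGT characters break tracts; input is uppercased.

Two deliberate restrictions: mono-, penta- and hexanucleotide repeats are
out of scope, and reverse-complement motifs are *not* collapsed —
transcript consensus sequences are stranded, so loci are reported on the
given strand only. Compound repeats such as `(AC)5TT(AC)4` are two
separate loci; only perfect tracts are considered.

## Read-level allele profiling

Pooled sequencing severs the link between read and individual, so
"alleles" here are read-level *length classes*, never diploid calls. A
read contributes a unit count only when it **spans** the tract: its
alignment must cover the tract plus `anchor_len` bases (default 5) of
flank on each side, and the aligned flank bases must match the contig
exactly. The read bases aligned within the tract (insertions inside the
tract included, deletions shrinking it) must form a whole number of
perfect motif copies; otherwise the read is **irregular** — tallied but
excluded from the histogram, because a single substitution would
otherwise masquerade as a new length allele. Counting uses the contig's
own tract rotation, not the canonical motif name.

From the histogram over counted reads: the number of in silico alleles is
the number of occupied length classes; the consensus genotype is the
modal class, ties broken toward the contig consensus count and then
toward the smaller count (a fixed, documented rule — assembly browsers
leave this implicit); off-consensus reads are those outside the consensus
class; `min_units_observed` (the shortest allele seen) is the length
predictor used in the downstream models. A locus is *variable in silico*
when some non-consensus class holds at least `min_minor_reads` reads. The
default of 1 mirrors manual practice of counting every discordant read as
evidence; raising it (2–4) discounts classes most likely to be slippage
errors — the error-vs-rare-allele trade-off is exactly one knob.

Primer-site screening counts aligned bases per reference column
(deletions and pads never contribute to depth); a column is a SNP when at
least two distinct bases each reach `snp_min_minor_reads` (default 2)
supporting reads, with minor allele frequency = minor count / depth. The
minimum column depth over the region is reported because shallow primer
sites cannot exclude a null allele even when no SNP is visible.

## Candidate selection

Filters mirror standard marker-development practice: minimum flank length
per side (default 30 bp — enough for a primer with slack; a genuinely
open choice, as no established threshold exists), minimum read depth of
2× across tract and flanks, contig must be annotated and mapped to a
reference genome, and at most one locus per isogroup. The isogroup
representative is the locus with the most in silico alleles, ties by
spanning depth then locus id — deterministic and order-independent. Every
failed rule is recorded per locus, so selection is auditable and
idempotent. Note that with isogroup deduplication active, relaxing an
unrelated rule may admit a better representative and displace a
previously selected locus; monotonicity of selection holds only with the
deduplication off.

## Validation statistics

* `He` uses Nei's unbiased small-sample correction `2n/(2n−1)`, the
  convention of standard population-genetics software.
* Chakraborty's `r = (He − Ho)/(He + Ho)` is computed from unrounded
  values; it is legitimately negative when the true null frequency is
  near zero and samples are small. `He + Ho = 0` yields NA.
* The Hardy–Weinberg test conditions on observed allele counts: full
  enumeration of heterozygote counts for two alleles (Levene's
  distribution), otherwise seeded Monte-Carlo re-pairings of the allele
  vector with the add-one-corrected tail probability. Tables tied with
  the observed probability within a 1e−7 relative tolerance count toward
  the tail. When the second most common allele has fewer than two copies
  the test is NA — one carrier cannot show disequilibrium.
* The Fisher exact test enumerates the full hypergeometric support; the
  two-sided P sums point probabilities ≤ the observed one (the convention
  of common statistical software; ties again within 1e−7 relative
  tolerance). A zero margin gives P = 1.
* Category summaries report mean ± SE (sample SD/√n) of observed allele
  counts per selection arm with a one-way ANOVA across arms; a single
  arm, or an arm with n = 1, yields NA where appropriate.
* GLMs (binomial for polymorphic yes/no, Poisson for allele number) are
  simplified by backward deletion: at each step the term whose removal
  costs the least deviance is dropped unless that cost is significant at
  α = 0.05 under χ² with df equal to the parameter-count difference;
  ties in drop order resolve by larger P first, then term name. Complete
  separation is flagged, not raised; fewer complete cases than parameters
  is an error. Deviance is non-increasing in the term set, so the reduced
  model never explains more deviance than the full one.
* Multiple testing uses Hochberg's step-up procedure.

## The simulator

The generator emulates the pooled-panel discovery design: by default 12
diploid individuals, mean depth 19×, reads of mean length 286 bp
(SD 30, truncated at the haplotype length), one microsatellite per
contig between 150 bp random flanks. Individual genotypes are drawn
independently from each locus's allele-frequency spectrum
(Hardy–Weinberg); each read picks a random individual and haplotype and a
uniform start. Two error processes: per-base substitutions (default
0.005, a 454-like scale) and whole-unit slippage (default 0.01 per
spanning read), which adds or removes one full motif copy — so at a truly
monomorphic locus the off-consensus read fraction estimates the slippage
rate, reproducing the sequencing-error/rare-allele confound as a tunable
property. Slippage is whole-unit by construction because in silico
alleles are length classes; partial-unit corruption arises from
substitutions and surfaces as irregular reads.

Alignments are constructed analytically from the known
haplotype-to-consensus correspondence: copy-number differences appear as
insertions/deletions of whole copies placed at the right edge of the
matched copies inside the tract, insertions that would hang off an
alignment edge are soft-clipped, and edge deletions are trimmed. Reads
are single-end, forward-strand, with no quality model; flowgram-level
noise, strand effects, per-individual template-quality differences, GC
bias and chimeras are all *not* modelled. Passing tests on this generator
therefore demonstrate correctness of the counting and statistics under
idealised alignments, not robustness to real aligner behaviour around
repeats.

A stochastic PCR outcome model (`amplify_prob`, default 0.76 as a
realistic conversion scale; `polymorphic_given_variable`; a genotyping
panel of 24 individuals redrawn from the same spectra) joins truth and
profiles into the validation-table schema, so the concordance and GLM
stages can be exercised end to end on synthetic data.

## Problem sizes and tolerances in the test suite

Scanner correctness is checked against an exhaustive per-(start, period)
enumeration oracle on ~250 generated sequences with planted tracts plus
seeded random 2–3 kb sequences. Profiler recovery uses 300 seeded
replicates of a two-allele (0.5/0.5) locus at 20× depth (≥ 99% two-allele
recovery expected; the analytic miss probability is ≈ 2·0.5¹⁸ per
replicate), and truth-set equality locus-by-locus on a 10-locus
zero-error simulation. Monte-Carlo HWE is compared with enumeration at
20,000 permutations within 3 binomial standard errors; type-I error uses
1,000 replicates at n = 24. GLM deletion-testing is validated on 120
logistic replicates (n = 200, one true effect β = 1.5, three noise terms)
and 100 Poisson replicates (slope 0.34, ~95% CI coverage). Slippage
calibration uses one deep locus (~10,000 spanning reads) within 3 MC
standard errors. These sizes keep the whole suite under a minute while
leaving the binomial/χ² bounds meaningful.

## Known limitations

* The scanner's smallest-period, run-anchored definition follows common
  SSR-search behaviour but other tools differ on compound and nested
  repeats; agreement is guaranteed only against the definition stated
  here.
* Profiles assume reads were aligned to the correct contig; paralog
  collapse or multi-mapping is not detected.
* The Chakraborty estimator from published, rounded Ho/He reproduces
  printed null-allele frequencies only to ~0.01.
* HWE exact enumeration is implemented for two alleles; multi-allelic
  P-values are Monte-Carlo (seeded, reproducible) rather than fully
  enumerated.
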