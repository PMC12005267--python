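# Methods

This note records the models, conventions and numerical choices behind
`trimsig`, and what the synthetic-data generators do and do not emulate.

## Coordinate and strand conventions

All positions are 1-based inclusive, the convention of both supported
variant dialects (VCF and VarScan2-style TSV); 0-based arithmetic is
confined to internal array indexing. Genomes are uppercase ACGTN.
Mutations at a contig edge or with an N in their trinucleotide context
have no defined pyrimidine-frame context; they raise a *skip signal*
that callers count and report (`skipped` in spectrum tables,
`n_skipped` in contingency tables) rather than silently dropping
records or aborting.

Spectra are strand-collapsed: a purine-reference SNV is reverse
complemented so the mutated base is reported as a pyrimidine, and its
3-mer context is complemented with it. Context strings use lowercase
flanks and an uppercase center (`gCa`), and the 96 categories are
`context>alt` labels (`gCa>A`).

## Variant curation

Three rules, applied with fixed precedence so the filter report always
partitions the input exactly:

1. **VAF ≥ 0.90**, boundary inclusive — a call at exactly the threshold
   is a homozygous-like call and is kept. VAFs are accepted as VarScan
   percent strings ("92.3%") or fractions and normalized to fractions.
2. **Baseline subtraction** — any key (contig, pos, ref, alt) present in
   the sequenced pre-treatment culture is removed.
3. **Shared-mutation removal** — any key carried by ≥ 2 *distinct*
   samples in the batch is removed from every carrier. Duplicate records
   inside one sample do not trigger the rule; different alt alleles at
   one site are distinct keys.

A record failing several rules is counted once, under the first.
Running the curation on its own output is a no-op (idempotence, tested).
The order VAF → baseline → shared is a package decision; the three
rules commute in which records survive, only the report's attribution
of fates depends on it.

## Windowed motif counting

For the enrichment background we count, in the window
`[pos − w, pos + w]` (default w = 20, mutated position included,
truncated at contig ends):

* `n_cyt` — cytosines on both strands, i.e. plus-strand C or G;
* `n_motif` — positions whose trinucleotide matches the signature motif
  on either strand. For gCn: plus-strand C with a 5′ G, or plus-strand
  G with a 3′ C (a minus-strand gCn cytosine).

Motif membership is a property of the genome position, not of the
window clip: a constrained flank (the g) is read even one base outside
the window, but must exist on the contig — a C at a contig start is not
a gCn cytosine. A wildcard `n` flank imposes nothing, so a 3′-terminal
gC still counts. One consequence of both-strand counting worth stating
prominently: a 5′-GC-3′ dinucleotide contributes **two** gCn cytosines,
one per strand — mirroring the strand collapse applied to mutations.
All counting is strand-flip invariant (tested by reverse-complementing
whole genomes and remapping coordinates).

Generic central-pyrimidine motifs (e.g. the APOBEC-style `tCw`) are
supported through IUPAC flank codes; genome N never satisfies a
constrained flank.

## The enrichment statistic

For one cohort — all isolates of a genotype × treatment condition
pooled, because per-isolate mutation counts in weak-mutagen screens are
too small for individual signature calls — the statistic is a ratio of
proportions:

```
E = (mut_sig / mut_all) / (ctx_sig / ctx_all)
```

with `mut_all` the strand-collapsed C→A count, `mut_sig` those in motif
context, and the `ctx` terms the summed window counts over each counted
C→A mutation's window. Background windows are drawn around the C→A
mutations only — the residues entering the test — keeping numerator and
denominator on the same residue set. Degenerate inputs yield explicit
markers, never smoothed estimates: no C→A mutations → undefined
(excluded from multiple-testing correction); `mut_sig = 0` → E = 0;
positive signal over a zero motif background → +∞. No pseudocounts.

Significance is a one-sided (greater) Fisher's exact test on the
disjoint 2×2 table `[[mut_sig, mut_all − mut_sig],
[ctx_sig, ctx_all − ctx_sig]]` — Fisher's test needs disjoint cells, so
the "signature vs all" phrasing is converted to "signature vs rest".
The Benjamini–Hochberg family is the set of cohorts analysed in one
call. The Fisher implementation is `scipy.stats.fisher_exact`,
cross-checked in the test suite against an exact rational-arithmetic
hypergeometric tail enumeration to 1e−12.

## Plating-assay model

Per culture, mutation frequency = Can^R colonies/mL ÷ viable
colonies/mL; viability % = 100 × treated viable density ÷ the median
untreated viable density of the same genotype (untreated cultures sit
at 100% by definition; the median reference is used because the input
schema carries no culture pairing). Fold change is the ratio of arm
medians (medians are what such experiments plot and report); a zero
untreated median yields an undefined marker, not infinity. The
Mann–Whitney U test is two-sided, exact for arms of ≤ 8 cultures and
tie-corrected normal beyond. Viability comparisons are exposed in two
modes — against the wild-type strain (default) or against the 100%
baseline — since both are meaningful reads of a survival assay.

qPCR fold changes are 2^−ΔΔCt with ΔCt = target − reference (ACT1)
channel and ΔΔCt taken against the mean wild-type ΔCt of the matching
growth condition; condition-mismatched pairings are hard errors.

## Synthetic-data generators

All generators run on `numpy.random.Generator` (PCG64) with explicit
integer seeds: bit-reproducible across platforms.

**Genomes** are i.i.d. base draws at a target GC (default 0.38,
yeast-like). They deliberately lack repeats, chromatin structure,
replication timing and mutation hotspots; passing calibration tests on
them shows the *statistic* is unbiased and correctly sized under its
own null, not that real genomes are this homogeneous.

**Signature spike-in.** C→A mutations are placed on cytosine sites
(either strand; minus-strand cytosines become G→T records), other
classes uniformly on their source bases, positions disjoint within and
across the samples of one call — independent isolates essentially never
acquire the same induced point mutation, and disjointness keeps
ground-truth fate labels exact. The probability `f` that a C→A lands on
a motif site is set by one of two modes:

* `calibration="windowed"` (default): `f` solves
  `f · (f·m̄ᶜₛ + (1−f)·m̄ᶜₙ) = E · (f·m̄ᵍₛ + (1−f)·m̄ᵍₙ)` (Brent's
  method), where m̄ᵍ/m̄ᶜ are the genome's exact mean window motif- and
  cytosine-counts around motif (s) and non-motif (n) sites. This makes
  the *windowed* enrichment estimator consistent for the target E: the
  naive alternative of multiplying selection odds by E leaves the
  estimator biased low (roughly E/(1 + (E−1)·bg) before window effects,
  and further because every motif mutation drags its own motif site and
  its partner-strand mate into the background window). Targets beyond
  what the genome's motif density can express raise an error rather
  than silently saturating.
* `calibration="odds"`: literal odds multiplication; at E = 1 it is
  exactly uniform placement over cytosines and is what the null
  calibration uses.

**Contamination** injects fresh baseline-resident keys, fresh keys
shared across random sample pairs, and sub-threshold VAFs
(uniform [0.2, 0.85]) on a stated fraction of original records,
returning an exact fate label per record. Injected contaminants keep
VAF 1.0 so each exercises the fate it was planted for.

**Assay simulation** layers Poisson colony counts (plating is a count
process; the plated volume is normalized to 1 mL) on lognormal
culture-to-culture frequency variation (default σ = 0.5, median-
parameterized so the injected fold is the median fold) and a fixed
untreated viable density of 2×10⁷ cells/mL with mild lognormal plating
noise (σ = 0.05). The treated arm's viable density is scaled by
1 − viability_drop (default 0.56, i.e. ~44% median viability).
Defaults — 12 cultures/arm, base frequency 1×10⁻⁶, fold 2.5 — represent
a repair-mutant acute-exposure experiment. The four-cohort study layout
(`simulate_study`) uses 17/19/27/28 isolates with the signature spiked
only in the deficient-treated cohort at E = 2.

## Problem sizes and tolerances

The statistical acceptance checks run at desk scale: 100 kb genomes;
1,000 null cohorts of 500 mutations (mean enrichment within 1 ± 0.05,
Fisher type-I ≤ 6% at α = 0.05 — the test is conservative here, ~1%,
because signature mutations inflate their own background); recovery of
E ∈ {1.5, 2, 3} at 2,000 C→A mutations within 10%; 200–500 assay
replicates (median recovered fold within 10% of 2.5; null rejection
≤ 7%). Oracle-equivalence tests (window counting, contingency
assembly, Fisher, BH) are exact, not tolerance-based. The null mean
enrichment sits ~3% below 1 at n = 500 — a small-sample ratio bias
(numerator and background are positively correlated) that vanishes as
cohort size grows.

## Known limitations

* The background convention (windows around C→A residues only, mutated
  position included, motif flanks readable beyond the window) is one of
  several defensible readings of windowed signature enrichment;
  other implementations may sum genome-wide motif totals instead.
* Multi-sample VCFs are rejected by design (one isolate per library);
  indels, MNVs and DBS spectra are out of scope, as is signature
  deconvolution against catalog signatures.
* The assay model ignores phenotypic lag, plating efficiency below 1,
  and jackpot (Luria–Delbrück) tails beyond what the lognormal captures;
  it reports frequencies, not mutation rates.
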