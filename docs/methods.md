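# Methods

This note documents the statistical models, conventions and design
decisions behind sweepscan, in the spirit of the model documentation that
accompanies packages like msprime or statsmodels.

## Coordinates and containers

All internal coordinates are 0-based half-open; conversion to 1-based VCF
and GFF3 happens only at I/O. Genotypes live in a
`(variants × samples × 2)` integer array (0 = ref, 1 = alt, −1 = missing);
the `phased` flag is true only if every genotype in the source used `|`.
Only biallelic SNPs are admitted; multiallelic and indel records are
skipped on read with a logged count.

## Synthetic panels

The generator is a Balding–Nichols model with founder-mosaic haplotypes:

1. Per SNP an ancestral frequency *p* ~ U(0.05, 0.95) (the support avoids
   a flood of monomorphic sites; any that still arise are kept in the VCF
   and handled by the downstream site filter).
2. Each population's frequency *q* ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
   F = `fst_target` (F = 0 short-circuits to *q* = *p*). F is the expected
   FST of each population against the ancestral pool.
3. Haplotypes copy from `n_founders` founder haplotypes (founder alleles
   Bernoulli(*q*)), switching founders between adjacent SNPs with
   probability 1 − exp(−rate·gap), `mosaic_break_rate` per bp. Founder
   sharing is what makes r² decay with distance; no explicit recombination
   map is modelled.
4. Per site, allele counts are then resampled to a Binomial(2n, q) target
   count by flipping a minimal random set of haplotype alleles. This makes
   allele-frequency sampling exactly binomial — the sampling model the
   Weir–Cockerham estimator corrects for — so the realized genome-wide FST
   recovers the Beta target closely (measured |error| < 0.01 at
   F ∈ {0, 0.05, 0.15}) while leaving most founder LD intact.

Defaults (3 populations × 15 samples, two 10-Mb chromosomes at
200 SNPs/Mb, F = 0.15, 12 founders, break rate 1e−5/bp) are sized to a
small resequencing panel of moderately differentiated breeds; densities
and chromosome counts are deliberately desk-scale — real whole-genome
panels are ~100× larger, and every statistic here scales linearly in
SNP count.

**Planted sweeps.** Within the target interval the derived (alt) allele
frequency is raised to at least `derived_freq` per SNP, then a fraction
`founder_fraction` of core-allele carriers is overwritten with the sweep
founder haplotype, defined as the all-derived haplotype. That choice makes
the interval's Hp response provably monotone in `founder_fraction`
(copying the all-derived haplotype can only push sites toward fixation)
and creates exactly the long shared haplotype XP-EHH targets. Carrier
subsets are nested, so increasing the fraction never reintroduces
diversity. With `derived_freq = 1` and `founder_fraction = 1` the interval
is monomorphic and window Hp is exactly 0.

**Planted ROH.** The sample's second haplotype is overwritten by its first
over the interval, so every covered SNP is homozygous; the truth record
keeps the interval.

What the generator does **not** emulate: genotyping error, allele-frequency
spectra from real demography (frequencies are uniform-ancestral, not
SFS-shaped), gene conversion, variable recombination, linked background
selection, and soft or incomplete sweeps. Passing the recovery experiments
therefore shows the estimators and the detection logic are correct, not
that the thresholds are well calibrated for any particular real dataset.

## Variant filtering

Hard filters follow the GATK convention: a record is removed iff a
*present* annotation violates QD < 10, ReadPosRankSum < −8, FS > 10,
QUAL < 30 or DP < 4 (all configurable). The thresholds are stated in the
literature as "filter settings" without an explicit direction; exclusion
of the failing records is the only sensible reading and is what we
implement. Missing annotations do not remove a record (GATK annotations
are legitimately absent at some sites); a strict mode that removes on
absence is available. Site-level filtering keeps call rate ≥ 0.9 and
pooled MAF ≥ 0.01 by default.

Variant classification against gene models is purely positional (exon ⊃
gene ⊃ intergenic precedence, union semantics for overlapping intervals);
functional effect labels (synonymous / non-synonymous) are *consumed* from
annotation inputs, never computed — codon-aware effect prediction is out
of scope. The annotation summary computes category percentages against the
total variant count and effect percentages against the exonic count, with
the ns/s ratio as a plain quotient (NaN when the denominator is 0).

## Diversity and Hp

Per site: He = 2p(1−p) with p the population alt frequency over called
alleles; Ho = heterozygote fraction among fully called genotypes;
MAF = min(p, 1−p). Summaries are unweighted means over sites polymorphic
in the population, and FIS = 1 − mean(Ho)/mean(He) (ratio of means — the
per-site ratio is unstable at small He).

The window statistic is the Rubin-style pooled heterozygosity
`Hp = 2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)²`, sums over the SNPs of the window.
Major/minor is assigned per SNP from the population's pooled counts; on an
exact tie the reference allele counts as major (deterministic). Windows
are 100 kb sliding by 50 kb, starting at 0 and truncated at the chromosome
end; trailing partial windows are emitted and scored when they hold at
least `min_snps` SNPs (default 10 — windows below it carry no score and
are excluded from the Z-transformation). Z-scores use the sample standard
deviation (ddof = 1) across all windows with a defined score; a
zero-spread input warns and yields all-undefined scores.

## FST

Per-locus Weir–Cockerham (1984) components for two populations (r = 2):
with n_i the called sample sizes, p_i the sample frequencies, h_i the
observed heterozygote fractions, n̄, n_c, p̄, s², h̄ as in the original
paper,

- a = (n̄/n_c)[s² − (p̄q̄ − s²/2 − h̄/4)/(n̄−1)]
- b = (n̄/(n̄−1))[p̄q̄ − s²/2 − h̄(2n̄−1)/(4n̄)]
- c = h̄/2

Components are undefined where a population has no called genotypes,
n̄ ≤ 1, or the locus is monomorphic across both populations (such loci
contribute nothing, matching standard practice). Negative estimates are
retained — clamping at 0 would distort the Z distribution. The window
statistic is the ratio of sums Σa/Σ(a+b+c) (the "weighted" windowed FST of
vcftools); mean-of-ratios is available behind a flag for comparison.
Whether a published "averaged FST across windows" means one or the other
is often ambiguous; ratio-of-sums is the default because it is what the
standard tool emits. Z-scores are computed per population pair across that
pair's windows only.

## XP-EHH

EHH at a core SNP is computed over **all** haplotypes of a population (the
cross-population convention — not stratified by core allele as in iHS),
extending SNP by SNP: EHH(x) = Σ C(n_h,2)/C(n,2) over groups of
haplotypes identical from the core through x. Missing alleles break
identity (each missing entry becomes a singleton; a match-through-missing
mode would be anti-conservative and is not default). iHH is the
trapezoidal integral over physical distance in bp, both directions,
truncated at EHH < 0.05 (the trapezoid reaching the first sub-cutoff
point is included) and at inter-SNP gaps > 200 kb (the segment spanning
the gap is excluded). These integration conventions are the standard ones
for this statistic family; nothing in the source material pins them down,
and all are configurable. Genetic-map (cM) integration is out of scope.

raw XP-EHH = ln(iHH_A/iHH_B) per core where both integrals are positive
(a zero integral makes the SNP undefined, not an error). Normalization is
genome-wide mean/sd (ddof = 1) — frequency-binned normalization belongs to
iHS, not XP-EHH. Tail extraction supports both the empirical top-q rule
(default, q = 0.01 per requested tail) and a two-sided normal p ≤ 0.01
rule; both appear in the applied literature and the empirical rule is the
default because it is the operative criterion in practice. SNP hits are
lifted to windows (score = max |norm| in window) before any cross-method
intersection, since Hp/FST operate at window level.

## ROH and LD

ROH detection mirrors the PLINK scanning-window algorithm with the full
default flag set (window 5000 kb / 50 SNPs / 1 het / 5 missing; emit at
≥ 10 SNPs, ≥ 200 kb, ≤ 50 kb/SNP density, split at gaps > 1000 kb). The
hit threshold 0.05 is the tool's own default, which the flag sets in the
literature usually omit. Both homozygous-ref and homozygous-alt calls
count as homozygous. Candidate runs are trimmed to homozygous called
endpoints. Boundary precision is inherently limited by the window
mechanism: an interval edge SNP is covered by at most a couple of fully
passing windows, so recovered boundaries sit within about one inter-SNP
gap of the truth when the flanking region is heterozygote-rich; the
recovery experiment measures the error against the first/last SNP inside
the planted interval for exactly that reason, using a fixture whose
flanks are fully heterozygous (the sharpest detectable boundary).

LD decay is the binned mean of haplotype r² = D²/(p_A q_A p_B q_B) over
all same-chromosome SNP pairs within 300 kb, 5-kb bins (stand-ins for a
decay tool's "default parameters", which are version-dependent;
configurable). Phased haplotypes are used directly; no EM for unphased
data. No decay-curve fitting is performed.

## Structure

PCA follows the smartpca convention: alt dosages, per-site mean
imputation of missing values, centering, scaling by √(2p̂(1−p̂)), then an
SVD of the sample matrix; monomorphic sites are dropped. Whether to scale
at all is a genuine choice — unscaled PCA weights common variants more —
and the tool convention is adopted. p-distances are allele-sharing
distances (0 / 0.5 / 1 per co-called site, pairwise deletion of missing
data). Neighbor joining is the Saitou–Nei algorithm with the standard Q
criterion; ties break deterministically on the lexicographically smallest
label pair, and negative branch lengths are clamped to zero with the
deficit moved to the sister branch (pair sums preserved). NJ is consistent
on additive matrices, which the tests exploit.

## Reporting and enrichment

Significant windows (ZHp < −4, ZFst > 4, XP-EHH tail) merge into maximal
regions when overlapping or book-ended (gap ≤ 0 by default: sliding
windows already overlap by construction). A gene is assigned to a region
on ≥ 1 bp overlap, half-open. Enrichment is the upper-tail hypergeometric
test P(X ≥ k) per term against the full gene-model background; raw
p ≤ 0.05 is the significance flag (matching common practice in the
applied literature, which rarely corrects), with Benjamini–Hochberg
adjusted values always reported alongside.

## Problem sizes and determinism

The recovery experiments use desk-scale panels chosen as the smallest
sizes at which the effects are unambiguous: FST recovery with 3 × 30
samples and 20 000 SNPs; sweep detection with 2 × 30 samples on 10 + 6 Mb
chromosomes at 200 SNPs/Mb (≈ 315 windows, enough for stable Z-scores);
ROH recovery on a 6-Mb chromosome at 200 SNPs/Mb. All randomness flows
from a single integer seed through `numpy.random.default_rng`; identical
configuration implies byte-identical outputs, which the tests assert.

## Known limitations

Two-population FST only (no multi-population estimator, no block
jackknife); no iHS/nSL; no phasing (input must be phased); no ontology
propagation in enrichment; the simulator's LD is mosaic-generated, not
recombination-map-generated, so its decay curve has the right shape but
no biologically calibrated scale.
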