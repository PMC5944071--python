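# Methods

This note documents the statistical model, the numerical choices, the
synthetic study conditions the test suite runs under, and the design
decisions taken where more than one reasonable reading existed.

## Data model and scope

The engine operates downstream of alignment and candidate-site discovery.
Its inputs are: a reference genome (FASTA); per-sample per-position depth
tracks (bedGraph, 0-based half-open); a candidate-site counts table
(tab-delimited; 1-based positions; comma-separated allele list with the
reference allele first; per sample one `top:bottom` pair per allele); a
sample sheet naming exactly one t0 ancestor and its outgrowths with their
ploidies; and optional BED files for exclusions and per-position copy
number.  Insertion and deletion alleles are full, left-anchored sequence
strings (a one-base deletion from `AA` is `REF=AA, ALT=A`), so an allele's
implied repeat-tract length is the site tract length plus its length
difference from the reference allele.

Reads, BAMs and the upstream caller are out of scope; an adapter converting
any caller's per-sample strand counts into the table above is the extension
point.  Because traversing coverage of a repeat cannot be inferred from a
depth track (depth includes partially overlapping, uninformative reads),
per-repeat traversing-coverage observations are a separate input supplied
by the adapter or the generator, via an optional `observations_path` column
in the sample sheet.

## Per-sample models

**Depth.**  Depths are divided by local copy number (copy-number map where
provided, sample ploidy elsewhere) and a Gaussian is fitted by non-linear
least squares to the integer-binned histogram rather than by moments: the
histogram fit is insensitive to the heavy right tail that repetitive
regions produce.  Constant tracks are rejected as degenerate.  Abnormal
regions: per-copy depths are averaged in a centred 25-bp window (edge
windows truncated), converted to two-tailed Gaussian p-values, and
significant positions (p < 1e-4) on the same side of the mean within
1000 bp of each other bound a region, emitted as 0-based half-open BED.
Both window centring and the same-side rule are choices documented here
because either could be defined otherwise.

**Strand bias.**  ln((top+1)/(bottom+1)) over all sites with any coverage;
the +1 per strand avoids division by zero and shrinks low-coverage ratios
toward zero.  A Gaussian is fitted to the histogram of these values.  The
two-tailed p-value of a new observation is 2·min(Φ(z), 1−Φ(z)).

**Repeat indel error.**  For each (event ∈ {insertion, deletion}, unit
length 1–4, tract length) stratum the error rate is Σ indel reads /
Σ traversing coverage; tract lengths with fewer than 10 distinct loci are
excluded from fitting; at least 4 usable lengths are required, otherwise
the caller falls back to the stratum's empirical rate (0 when absent).
The logistic fit is initialised at M = min rate, L = max−min, k = 1,
x0 = median length with bounds M, L ≥ 0, k ∈ (0, 10], x0 within the data
range ± 5.  Predictions are clamped to [0, 0.5] so extreme extrapolation
can never move more than half of an allele's expected mass.

**Chromosome-end depth bias.**  Ratios to the genome-wide mean are binned
by distance to the nearest chromosome end (500 bp bins), per-bin medians
are taken after excluding ratios above 4 or below 0.25, and
`factor(x) = scalar·(1 − lognormCDF(x; μ, σ)) + intercept + slope·x` is
fitted by trust-region least squares.  Correction divides each position's
depth by factor(distance); zeros are preserved.  The module is optional and
idempotent to within fit noise (re-fitting a corrected track yields
scalar ≈ 0).

## Genotype calling

All clonal allele multisets of cardinality = local copy number over the
site's observed alleles are enumerated; each clonal genotype spawns
subclonal variants replacing exactly one allele with a different observed
allele, at fractions 0.500, 0.250 and 0.125 (mutations in the first,
second or third post-bottleneck division; the same fraction set is applied
at every ploidy).  Expected frequencies are the fraction-weighted mixture
of clonal and subclonal allele proportions.  In repeat context, each
genotype allele's expected mass leaks to its single-unit neighbours at the
fitted insertion/deletion rates evaluated at that allele's implied tract
length; mass is conserved, and deleting the entire allele is not
representable so that path's rate is zeroed.  Zero expected frequencies
are then floored at 2/total depth.

Scoring, `Σ |ln(o/e)|`, runs over the alleles observed with non-zero
frequency in the sample.  Two boundary conventions matter and are
deliberate: (1) an observed allele the model omits is scored against the
2/depth floor, penalising models that ignore real alleles; (2) alleles the
correction predicts but that carry no reads contribute nothing — flooring
their observed side instead would let the pseudo-count (≈ 0.04 at 50×)
dwarf the predicted error mass (≈ 10⁻³) and systematically flip clean
homozygous repeat sites to heterozygous calls.  No renormalisation is done
after flooring; scores are only compared within a site.  Ties (within
1e-9) go to the genotype with the most reference alleles (t0) or the most
alleles shared with the t0 call (outgrowths), then lexicographically for
determinism.

A called subclonal component is kept only if its pooled read count is
binomially incompatible (upper tail, p ≤ Šidák α) with its expected
frequency under the clonal-only model — the floored 2/depth when the
clonal model gives it no mass — and its strand ratio is not extreme
(two-tailed p ≥ α) under the genome-wide distribution.  A t0 subclonal
call reverted for strand bias suppresses mutation reporting at that
position entirely.

## Mutation identification

The chi-square test compares outgrowth counts per allele × strand against
expectations formed from t0 cell proportions with +1 added to every t0
cell (df = 2·alleles − 1); the pseudo-count convention avoids zero
expectations and is a documented choice.  Binomial tests per allele and
strand use the outgrowth strand total as trials and the t0 strand fraction
as success probability, replaced by 1/(strand total + 1) where the t0
count is zero.  The composite score threshold is the per-axis bound
−log₁₀ α applied to the vector magnitude — the conservative reading of the
two plausible conventions (the alternative √3-scaled bound would call
more).  n_tests = genome length minus excluded and abnormal positions,
computed per outgrowth.

Sites where either sample's reads all lie on one strand, or fewer than two
alleles carry reads across both samples, are excluded before testing: a
literal per-sample single-allele exclusion would remove every true
mutation site (the t0 always shows one allele there), so the conjunctive
form is used.

Filter order: user exclusion, abnormal depth (either sample), depth < 20
(either sample), t0 subclonal strand bias, single-strand/single-allele,
statistical thresholds.  The pipeline calls genotypes only at sites whose
statistics fire; sites failing the statistical rule are labelled
below_threshold without evaluating the (genotype-dependent) t0 bias
condition.  Records are emitted for statistically notable sites (any
allele's composite above threshold); a site passing all filters whose
genotype calls agree produces no record, because a mutation is a genotype
difference.

## Mutation identity

Breadth-first search over genotype multisets with three event kinds:
conversion of one copy to any observed allele, gain of any observed
allele, loss of one present copy (never the last).  The depth cap is
|Δcardinality| + differing alleles + 2.  All shortest paths are returned
in lexicographic order; events are compared as multisets (A|A → C|C needs
the same conversion twice).  Certain events are the multiset intersection
across paths; leftover events group into an ambiguous event when every
path contains a member — conversions group by starting allele, gains and
losses by kind (their "starting allele" is the copy-number change itself).
PAC: a conversion whose target pre-exists in t0 with unchanged
cardinality; ambiguous when only some targets of an ambiguity group
pre-exist.  PAC is a per-site flag; clustering across sites is left to
downstream analysis.

Naming: reference substitutions `g.1000A>C`; single-unit deletions and
insertions in HGVS del/ins form anchored at the tract
(`g.1003del`, `g.1003_1004insA`); mutations within a non-reference allele
via flanking positions (`g.999_1001G>C`); copy-number events with
`gain`/`loss` keywords and `*` for ambiguous alleles; ambiguous
alternatives pipe-joined.

## Rates and simulation

μ_bp = N/(N_bp·gen_tot), with N_bp set to the global ploidy for
whole-genome rates.  The false-negative model sums the binomial CDF
B = Σ_{x=0}^{L} C(n, x) pˣ (1−p)ⁿ⁻ˣ with n = round(D·C) trials and
traversal probability p = (R − 2(L+δL))/(R − (L+δL)); the printed source
formula's coefficient index is read as the standard CDF term, and δL (the
length inflation of the indel allele) defaults to 1 and is configurable.
The Monte Carlo walks each homopolymer's length ±1/0 per generation at the
per-length rates, re-indexing rates by current length each generation and
clamping lookups to the table's range; a net decrease ≥ 2 counts as a
multi-base deletion, and the result exposes means, central 95% envelopes
and an exceeds-envelope comparison hook.

## Synthetic study conditions

The generator's defaults are the conditions the tests run under: diploid,
depth Normal(50, 6) per position, strand-split by a per-site ln-ratio
drawn Normal(0, 0.2), per-read substitution error 10⁻³ (a realistic
post-quality-filter Illumina rate; errors at a site go to one alternative
base, so error sites are biallelic), read length 150, and logistic
slippage parameters per unit length with the homopolymer deletion curve
(M = 0.001, L = 0.15, k = 0.9, x0 = 10) rising to ≈ 0.15 per traversing
read in long tracts, insertions slightly lower and longer units flatter.
Candidate sites are those with any non-reference evidence in either
sample, mirroring a sensitive caller's site selection.  Traversing
coverage of a tract is binomial in the mid-tract depth with traversal
probability (R − 2(L+1))/(R − (L+1)) clamped to [0.05, 1].  A
deterministic expectation mode (counts = rounded expected values, exact
50/50 strand split) supports exact unit tests.

What the generator does not emulate: mapping artefacts with positional
structure, correlated errors between samples, multi-allelic substitution
errors, CNVs beyond user-planted abnormal regions, and contamination.
Passing tests therefore demonstrate correctness of the statistical engine
under its own model assumptions, not robustness to every artefact of real
alignments — the region filters and strand-bias machinery exist precisely
for those, and are exercised only through planted analogues.

Problem sizes in the test suite were chosen to be informative at desk
scale: family-wise error control uses 50 replicate 1-Mbp genome pairs at
50× (no planted mutations; the pass criterion is ≤ 10% of replicates with
any call, a loose bound around the nominal 1% FWER given model misfit);
sensitivity uses five 1-Mbp genomes with 150 clonal substitutions and 50
single-unit repeat indels in tracts ≤ 10 bp each; parameter-recovery runs
use 10⁵–10⁶ positions.  The error-model recovery fixture plants seven
repeats of every length 4–18 for units A and C at 200× so all strata clear
the 10-locus fitting rule.

## Known limitations

Subclonal fractions outside {1/2, 1/4, 1/8} (e.g. tumour heterogeneity)
are out of scope by design.  The GenotypeCall records the differentiating
subclonal allele and fraction, not the full subclonal multiset; when one
clonal allele could have been replaced in more than one way the
representation is lossy (the reported events are unaffected).  The repeat
definition admits 1⅓-unit tracts of unit length 3–4 (total length ≥ 4 bp),
which makes the repeat list large on random sequence; the per-sample error
model simply measures near-zero rates for those strata.  VCF output
records one line per mutation position per sample with the event in INFO,
not a multi-sample genotype matrix.
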