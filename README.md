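# macall

Calling accumulated mutations in mutation-accumulation (MA) experiments:
a founding clone (the *t0* ancestor) is propagated through repeated
single-cell bottlenecks, the descendants (*outgrowths*) are sequenced, and
every t0-vs-outgrowth difference is an accumulated mutation.  The hard part
is not finding candidate variants — it is deciding which of the thousands of
candidate sites reflect a real genotype change rather than mapping
artefacts, abnormal copy number, strand-biased mismapping, or PCR slippage
in simple repeats.

`macall` is a library and CLI for that decision.  It consumes
strand-specific allele-count tables at candidate sites (the adapter contract
standing in for a local-reassembly variant caller), per-sample depth tracks
(bedGraph) and a reference genome (FASTA), and produces filtered mutation
calls in TSV and VCF form.

## The statistical engine

**Per-sample empirical models.**  Per-copy read depth is modelled as a
Gaussian fitted by least squares to the depth histogram; 25-bp windowed
means in its far tails (two-tailed *p* < 10⁻⁴, merged within 1 kb) mark
abnormal-depth regions that are filtered.  Strand bias ln(top/bottom) is
modelled as a second Gaussian.  Slippage indel errors in simple repeats
(unit length 1–4 nt, tract length ≥ 4 bp) are counted from reads that fully
traverse each tract and fitted, per event type and unit length, with a
four-parameter logistic in tract length *x*:

    error(x) = M + L / (1 + exp(-k (x - x0)))

An optional chromosome-end depth-bias model
`factor(x) = scalar·(1 − lognormCDF(x; μ, σ)) + intercept + slope·x`
rescales depth by 1/factor before re-analysis.

**Genotype calling.**  At each site all clonal genotypes (allele multisets
of cardinality = local copy number) and one-allele-different subclonal
variants at fractions 1/2, 1/4, 1/8 are enumerated.  Expected allele
frequencies are corrected for single-unit slippage using the fitted error
rates, zero frequencies are floored at 2/depth (one pseudo-count per
strand), and each model is scored with

    score = Σᵢ |ln(oᵢ / eᵢ)|

over the observed alleles; the minimum-score model wins.  Subclonal
components must additionally pass an upper-tail binomial test against the
clonal-only expectation at the Šidák-corrected threshold
α = 1 − (1 − FWER)^(1/n), n = queryable genome positions, and a two-tailed
strand-bias test against the genome-wide distribution.

**Mutation identification.**  Outgrowth counts are compared to t0 with a
chi-square goodness-of-fit test over alleles × strands (*p_chi*) and
per-allele, per-strand upper-tail binomial tests (*p_top*, *p_bottom*).
The composite score

    score = √((−log₁₀ p_top)² + (−log₁₀ p_bottom)² + (−log₁₀ p_chi)²)

is the distance from certainty that no mutation occurred.  A site is called
when *p_chi* < 0.1 and some allele has composite score above
−log₁₀ α with both strand *p*-values < 0.1 — the both-strands requirement
suppresses calls driven by mismapped single-strand reads.  Filters (user
exclusions, abnormal depth, depth < 20, t0 subclonal strand bias,
single-strand/single-allele coverage) populate the VCF FILTER field.

**Mutation identity.**  For each called site the most parsimonious event
sequences (conversions, copy-number gains, losses) from the t0 genotype to
the outgrowth genotype are enumerated breadth-first; events shared by all
shortest paths are reported as certain, the remainder grouped into
ambiguous events (`g.1000A>C|g.1000A>G`).  Conversions that increase a
pre-existing allele without changing copy number are flagged PAC (potential
allelic conversion).  Names follow HGVS style with `gain`/`loss` keywords
for copy-number events.

**Downstream.**  Mutation rates μ = N/(N_bp·generations); the legacy
false-negative correction B(L; D, p) for allelic-fraction-cutoff callers;
and a Monte Carlo of single-base slippage accumulation in homopolymers with
95% envelopes, for asking whether observed multi-base deletions exceed what
sequential single-base events explain.

A first-class synthetic-data generator (`macall.synth`) emulates the whole
data model — clonal/subclonal genotypes, per-strand binomial sampling,
log-normal strand bias, depth variation with optional end bias and abnormal
regions, and logistic repeat slippage — so the engine is testable end to
end without any external data.

## Worked example

```
$ macall simulate-dataset ex --seed 11 --length 50000 --mutations 6 --indel-mutations 2
dataset with 5882 candidate sites and 8 planted mutations -> ex
$ macall run-pipeline ex/samples.tsv ex/reference.fa ex/out --repeat-file ex/repeats.tsv
outgrowth: 8 mutations pass / 27 records
```

All eight planted mutations (six substitutions, one single-unit repeat
deletion, one insertion) are recovered and nothing else passes:

```
$ awk -F'\t' '$15=="pass" {print $1, $2, $8, $9}' ex/out/outgrowth.mutations.tsv
chr1 3697 g.3697T>A no
chr1 10206 g.10206G>T no
chr1 14007 g.14007G>T no
chr1 15361 g.15365del no
chr1 30803 g.30803A>G no
chr1 44849 g.44855_44856insT no
chr1 46723 g.46723T>A no
chr1 48157 g.48157A>C no
```

Columns are chromosome, position, HGVS-style event name and PAC flag; the
19 non-passing records are statistically notable sites rejected by the
decision rule or filters, retained in the output with their filter status.
The fitted per-sample models land on the generating truth (depth 50× on a
diploid → per-copy mean 25, σ 3; strand-bias ln-ratio mean ≈ 0):

```
$ head -5 ex/out/t0.models.txt
sample       t0
depth_mean   25.2672
depth_std    3.01919
strand_bias_mean  -0.000780656
strand_bias_std   0.331373
```

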