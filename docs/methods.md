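# Methods

`rilsim` models the construction of inter-population recombinant inbred lines
(RIL) in a selfing hermaphrodite / X0-male nematode (*Caenorhabditis
briggsae*, founder populations AF16 and HK104) and the transmission-ratio-
distortion (TRD) statistics used to detect selection — in particular
mito-nuclear Dobzhansky-Muller incompatibilities (DMIs) — from the genotypes
of the surviving lines.

## Genome and genotype model

Only ancestry is tracked, not sequence. A haplotype is an ordered list of
intervals over `[0, length)` (0-based, half-open, bp) labelled `AF16` or
`HK104`; founders are single-segment haplotypes because both isolates are
fully homozygous selfers. An individual carries five autosome pairs, two X
copies (hermaphrodite) or one (X0 male), and a single mitotype label —
heteroplasmy is unrepresentable by construction, matching the absence of any
observed heteroplasmy in these crosses. Markers read the ancestry at a point;
a mitochondrial marker reads the mitotype. Genotype tables (lines × markers,
calls `AA`/`HH`/`AH`/`NA`, plus design, cross direction and mitotype metadata)
are plain CSV/TSV and round-trip byte-stably.

Chromosome lengths and most marker positions are not analysis inputs in any
quantitative sense — every statistic here depends only on which chromosome a
marker sits on — so the bundled genome spec uses approximate assembly sizes
and the bundled 11-marker panel uses placeholder positions except where a
placement is anchored (cb-m205 on III, cb-m124/cb-m127 on X, cb51757 at
X:12,000,000, cb18178 on MT, no marker on chromosome I). Which AFLP assay is
the third X marker is not established; the panel assigns cb-m197 and marks it
unanchored. Both files are user-overridable CSVs.

## Breeding-design simulator

Both designs start from a P0 cross of a male of one population to a
self-sperm-depleted hermaphrodite of the other, so F1 hermaphrodites are
heterozygous genome-wide, F1 males carry the maternal X, and every descendant
inherits the maternal mitotype.

* **AI-RIL** (default): 7 rounds of sibling mating, 3 mated hermaphrodites
  (each paired with a sibling male) per round, then 10 generations of
  single-hermaphrodite selfing.
* **F2 RIL**: 2 sibling-mating rounds with a single mated hermaphrodite, then
  the same selfing phase. Because descriptions of this design vary in how they count the minimal
  intercross rounds, the schedule is configurable.

Meiosis defaults to an obligate single crossover per bivalent at a uniform
position — the expected behaviour under the near-complete crossover
interference of *Caenorhabditis* — with a Poisson(rate) mode for sensitivity
analysis. The male's hemizygous X never recombines and is transmitted intact
to exactly half of his sperm (Bernoulli 1/2 per gamete); nullo-X sperm sire
X0 males. Selfed offspring are all hermaphrodites; the ~0.1% X-nondisjunction
male rate in real *Caenorhabditis* is ignored as negligible at these scales.

Selection is viability selection: each offspring survives with probability
equal to its fitness, the product of `(1 - s)` over triggered DMI terms. A
term names two loci (one may be the mitochondrial genome), an incompatible
allele at each, a penalty `s ∈ [0, 1]` and a trigger rule — `recessive`
(homozygous, or hemizygous on the male X) or `dominant` (any copy). The
underlying fitness mechanisms in the real lines (developmental-delay
competition, fecundity, embryonic lethality) are not quantified anywhere, so
`s` is a free model parameter; `s = 1` with a recessive trigger encodes the
absolute mito-X exclusion pattern seen in the AI-RIL data.

Brood size defaults to 10 offspring per mated (or selfed) hermaphrodite — a
pragmatic stand-in for unreported brood sizes and within-plate competition;
it sets the strength of within-brood selection relative to drift.
`self_to_fixation` extends the selfing phase until all nuclear panel markers
are homozygous (per-locus heterozygosity halves each selfing generation, so
this adds few generations).

Replicate `r` of a run uses the RNG substream `(master_seed, r, restart)`:
replicates are independent and individually reproducible, and a replicate
that goes extinct (no viable offspring, or too few hermaphrodites/males to
continue) is restarted on a fresh substream rather than dropped — mirroring
that only completed lines are ever genotyped — with restarts logged so the
conditioning bias is measurable. A replicate restarting 100 times aborts the
run with a diagnostic (the DMI model is effectively lethal for the design).
Identical inputs and seed give a bit-identical genotype table.

Under neutrality the simulator recovers the design nulls from first
principles rather than by construction: autosomal fixation is 1/2, and the X
fixes the maternal allele with probability 2/3 because the X copies entering
a line through the breeding F1s stand in a 2:1 maternal:paternal ratio (each
F1 hermaphrodite carries one of each; each F1 male carries a maternal X).

## TRD statistics

TRD at a marker is the fraction of focal-population alleles over all lines of
one cross direction: two per homozygous line, one per heterozygous line
(TRD is defined over alleles, not lines; an unfixed line contributes one
allele to each side), missing calls excluded. Observed fractions are compared
to the null — 0.5 for autosomes; 2/3 maternal / 1/3 paternal for the X — by a
Pearson goodness-of-fit chi-square (df 1, no continuity correction) on the
two allele classes, Bonferroni-corrected (`alpha / n_tests`, e.g.
0.05 / 20 = 0.0025 for ten markers × two directions). Tests with an expected
class count below 1 are flagged unreliable rather than silently switched to
an exact test, preserving comparability across markers.

A caveat the package makes explicit: for fully inbred lines the two alleles
of a line are perfectly correlated, so the focal allele count is twice a
binomial over *lines* and has double the variance the allele-count chi-square
assumes. The realized per-test type-I error at nominal 0.0025 is therefore
~3.4% for 20-line panels — still well inside a 0.05 family budget, and
irrelevant for the absolute (p ≈ 10⁻⁵–10⁻⁶) signals of interest, but worth
knowing when interpreting marginal significance flags. The test suite checks
this against an exact binomial-over-lines oracle.

The drift argument is quantified as `per_line_prob ** n_lines`: the
probability that all n lines independently fix the same specified allele
(0.5²⁰ ≈ 9.5×10⁻⁷ for 20 lines; 0.5⁵ ≈ 3.1% for one marker on each of five
chromosomes).

Linkage disequilibrium is computed over line-level fixed alleles (lines
heterozygous or missing at either locus are excluded and counted; the
mitotype acts as a one-allele-per-line locus): `D = P(AB) − pA·pB`,
`D' = D/Dmax`, `r² = D²/(pA·qA·pB·qB)`, with `complete` flagged when
`|r² − 1| < 10⁻⁹`. A monomorphic locus leaves LD undefined and flagged — in
particular, a marker fixed in *every* line of one direction (the absolute-TRD
case) has no within-direction LD; complete mito-X association is visible as
r² = 1 on the two directions pooled, where both loci segregate.

Reciprocal-cross asymmetry contrasts the two directions at a marker with each
direction's TRD measured relative to its own maternal allele, so the
mirror-image mito-X pattern (HK104 fraction 1.00 in one direction, 0.00 in the
other) registers as Δ = 0, symmetric; a 2×2 allele-count × direction
chi-square tests homogeneity. Passing an explicit focal population compares
raw fractions instead.

Human-readable reports round fractions half-up to two decimals; machine
output keeps full precision.

## Synthetic fixtures

Line-level genotype data for experiments of this kind are rarely available
in machine-readable form, so `fixtures` generates tables with the same
statistical structure: exact per-marker counts of focal-fixed lines
(randomized line assignment, deterministic per seed), coupled marker groups
with identical per-line assignments (complete co-segregation), maternal
mitotypes, and optional unfixed (heterozygous) lines. The built-in suite
encodes the reference replicate counts (19/20/9/12) and X-marker fractions
(1.00/0.00/0.44/0.08); autosomal markers in the HK104-mitotype table are set
to 80% HK104-fixed lines — genome-wide HK104 bias in that direction is the
qualitative feature being emulated, and 80% is an assumption of this
generator, documented here, not a measured value. The third X marker is set to 17/19
(significant but not absolute, as only two of three X markers showed absolute
bias). A Bernoulli `neutral_fixture` draws each line's fixed allele from the
null (fair coin on autosomes, 2/3 maternal on X) for type-I-error studies.

What fixtures do *not* emulate: real linkage between markers on a chromosome
(fixture markers are independent unless coupled), residual heterozygosity
beyond the explicit unfixed-line count, genotyping error, and segregating
variation within founder populations. Tests passing on fixtures therefore
validate the statistics pipeline's arithmetic and decision rules, not the
population-genetic realism of any particular dataset — that is the
simulator's job, and the simulator-based tests cover it.

## Problem sizes and numerical choices

The neutral-recovery checks use 2,000 replicates per direction (Monte-Carlo
SE ≈ 0.008 on an allele fraction, comfortably inside the ±0.02 band the
checks use); unit-level invariant checks use 300 replicates with 3-SE bands.
Heterozygosity-decay checks follow 1,000–2,000 independent selfing lineages
for up to 10 generations. Chi-square oracle agreement is enumerated over all
small count instances (totals ≤ 60). Ties and degenerate inputs: a crossover
at position 0 degenerates to transmitting one parental strand (still a valid
single-crossover draw); `drift_probability(0) = 1` (empty product); zero
informative lines raise an undefined-result error rather than returning NaN.
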