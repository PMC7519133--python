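# Methods

`cqcov` re-implements, as a tested and reusable pipeline, the coverage-based
sex-chromosome inference used for fly genomes with homomorphic (morphologically
indistinguishable) sex chromosomes: chromosome-quotient classification of
putative X/Y contigs, Muller-element X-linkage testing, and coverage-histogram
decomposition with duplication-corrected genome-size estimation.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic data do and do not establish.

## The copy-number model

All statistics derive from one observation: the read depth a contig attracts
is proportional to its copy number in the sequenced genome.  In an XX/XY
system with a differentiated region,

* autosomal sequence carries 2 copies per diploid genome in both sexes
  (depth ratio female:male = 1),
* X-limited sequence carries 2 copies in females and 1 in males (ratio 2),
* Y-limited sequence carries 0 copies in females and 1 in males (ratio 0),
* a collapsed duplication — sequence present twice per haploid genome but
  assembled into a single contig — attracts twice the baseline depth in
  both sexes.

The synthetic-data generator (`cqcov.simulate`) emits exactly these classes.
A library's `mean_depth` is the fold-coverage of the ordinary two-copy state;
the expected read bases drawn from a contig of length *l* with *c* copies are
`mean_depth · l · c/2`.  Read counts are Poisson, start positions and strands
uniform, base errors i.i.d. substitutions (no indels: the zero-mismatch
criterion downstream makes substitutions the relevant perturbation).  Reads
are single-end even though such libraries are typically paired 2×100 bp:
every downstream statistic consumes per-read alignments only, so pairing
carries no extra information here.  Read names embed the contig of origin,
which is what lets oracle tests audit every stage against truth.

Repetitive Y material shared between the sexes is modelled by `y_leak`: a
contiguous prefix of a Y segment, covering a `y_leak` fraction of its bases,
is also present in the female genome at autosomal copy number.  This is the
simplest mechanism that produces small-but-nonzero female alignment counts on
Y contigs, and it is the reason the putative-Y threshold is 0.3 rather
than 0.

Default library depths mirror the three-library design of the study system
(arrhenogenic female 43X, thelygenic female 34X, male 28X); default GC is
0.35 (dipteran genomes are AT-rich).  Within-pool polymorphism (libraries
pooled from several individuals) is *not* modelled.

## Read matching

Two regimes, both ungapped and full-length, with `N` never matching anything
in either role:

* **EXACT** — a placement is a (read, offset, strand) triple at which the
  whole read equals the contig substring with zero mismatches.  Every
  placement is counted (a repetitive read contributes to every location),
  because the chromosome quotient is a ratio of *alignments*, not reads.
* **IDENT80** — a placement is admissible when its mismatch count is at most
  `floor((1 − min_identity) · L)`; each read contributes exactly one
  alignment at its best admissible placement (fewest mismatches; ties to
  the lexicographically lowest contig name, lowest offset, forward strand).
  One placement per read keeps the derived depth uninflated, which is what
  the Muller comparison needs.

Reverse-complement matching is on by default (library strand is unknowable).
A read that is its own reverse complement therefore carries one placement
per strand at the same offset — a deliberate consequence of the triple
definition.

Implementation: contigs are concatenated with a sentinel byte and every
length-*L* window is fingerprinted with an invertible 64-bit rolling hash;
candidate placements are verified against the actual sequence, so hash
collisions cannot reach the counts.  For EXACT the fingerprint covers the
whole read and the counter is provably equivalent to the naive scan.  For
IDENT80 two seeding strategies exist: a *q-gram* mode with seed length
`floor(L/(m+1))` (pigeonhole: any placement with ≤ m mismatches contains an
error-free seed, so the result equals an exhaustive scan) and a *seed* mode
with non-overlapping k-mers (k = 15 by default), complete for placements
with fewer than `L // k` mismatches and heuristic beyond.  `method="auto"`
uses the q-gram mode whenever the estimated candidate volume is small enough
and the heuristic otherwise; at the error rates the simulations use (0 to a
few percent) the heuristic's completeness bound is essentially never binding.

## Chromosome quotients

For contig *c*, `CQ(c) = (F_c/F_tot)/(M_c/M_tot)` with EXACT-regime counts;
`F_tot`, `M_tot` are library totals.  Library-size normalisation is **on**
by default: the textbook expectation CQ = 2 for X-linked contigs holds only
at equal effective depths, and real libraries differ (43X/34X/28X above).
The unnormalised mode reproduces the literal alignment-count ratio.
Normalisation presumes the two libraries sequence near-identical genome
content — true when the differentiated region is a small minority of the
genome.  If a large fraction of the reference is sex-linked, the female and
male totals themselves diverge and normalized CQs shrink toward 1 by the
factor `(R+½)/(R+1)` (R = autosome:X base ratio); synthetic benchmarks here
therefore embed sex-linked panels in an autosomal background roughly
19× their size, which keeps the shrinkage within ~2.5 %.

Bands follow the printed convention: putative Y below 0.3 (strict
inequality), putative X in [1.6, 2.5] (both ends inclusive).  A contig with
male count 0 but female evidence gets an infinite sentinel and stays
unclassified; fewer than `min_support = 10` combined alignments yields
LOW_EVIDENCE instead of a call (the support floor is this package's
addition — a CQ from a handful of reads is noise).

The dual-female representative X set (`consensus_x`) is a greedy cross-set
clustering honouring the 80 % identity / 80 % length-difference cutoffs of
the external clustering tool it stands in for: smaller set processed in
descending length, each contig matched to at most one unused contig of the
larger set when the shorter sequence reaches the identity bar at its best
ungapped placement (either strand) and the length ratio passes; the longer
member represents the pair.  It is an approximation of full
identity-clustering; an all-vs-all oracle bounds it in the tests.  The
proportion of overlap between the two putative-Y sets is computed relative
to the smaller set.

## Muller-element X-linkage

Anchored contigs (the anchor table stands in for homology-based Muller
assignment, which is out of scope) are compared between sexes under IDENT80
counts.  Counts are equalised with median-of-ratios size factors — for each
contig with a positive geometric mean across samples, the sample/reference
ratio is formed, and a sample's factor is the median of its ratios, rescaled
to geometric mean 1.  This is the standard normalisation of count-based
differential-coverage analysis, re-derived here rather than imported; the
pre-installed pydeseq2 implementation serves as an independent cross-check
in the test suite.  Dispersion estimation and hypothesis testing are
deliberately out of scope — only the normalisation is needed.

Per contig, `log2_mf = log2((M_c/f_M + ε)/(F_c/f_F + ε))` with pseudocount
ε = 0.5 guarding zeros (the source analysis is silent on this; the pipeline
reports the X-linked fraction at ε/2 and 2ε alongside as a sensitivity
check).  A contig is X-linked when the ratio lies in [−1.3, −0.6], inclusive
at both ends; the expectation for a 2:1 female:male copy ratio is −1.  The
band's endpoints are printed in descending order in the source convention
and their inclusivity is not stated; inclusive was chosen and is documented
here, not asserted as original intent.  An element is flagged sex-linked
when at least half of its anchored contigs are X-linked
(`flag_threshold = 0.5`, configurable; the source analysis reports only the
qualitative < 5 % observation).  The two female libraries are pooled by
default before the comparison (per-female mode available).

## Coverage mixture and genome size

The per-contig coverage histogram (one point per contig, weighted by contig
length; a per-base reading of the same data differs only in the weights) is
decomposed on the log2 axis with 1- and 2-component Gaussian mixtures fitted
by EM, the model chosen by BIC.  Two deliberate choices:

* **Tied variance.**  The two components share one log-scale variance.
  With free variances, a two-component fit can absorb the kurtosis of
  length-heterogeneous single-mode data (short contigs are noisier than
  long ones) and beat the one-component model on genuinely unimodal
  coverage.  Tying the variance encodes the actual hypothesis — two
  copy-number states of the same noise process — and keeps model selection
  honest: on simulated single-mode data the 1-component model wins BIC in
  ≥ 95 % of seeded runs.
* **Main-component trimming.**  Contigs above 100,000X (mapping artifacts,
  mirroring the source convention) and below 0.25× the weighted median
  (the near-zero tail: unsequenced or sex-limited material such as Y-leak
  contigs in a female library) are excluded from the *fit*.  Without the
  floor, a handful of near-zero outliers can hijack one component entirely.
  Excluded contigs still participate in the 1X/2X side assignment.

Numerics: initial means from weighted quantiles, 10 deterministic restarts
(first from the 25th/75th percentiles, the rest jittered by the seeded rng),
relative log-likelihood tolerance 1e−8, at most 500 iterations, sd floor
1e−6 (degenerate all-equal input collapses to one component with a warning).
With a tied variance the equal-density cutoff between the means is
closed-form: `x* = (μ₀+μ₁)/2 + σ²·ln(π₀/π₁)/(μ₁−μ₀)` on the log2 axis,
clamped between the means.  The major/minor peak-height ratio is the ratio
of the fitted density maxima on the *coverage* axis (where a component's
peak scales as 1/mean), located numerically on each side of the cutoff.

Genome size: contigs at or below the cutoff are 1X, contigs above are 2X
(assembled once, present twice), giving `estimate = bases_1x + 2·bases_2x`.
This formula is a re-derivation of the duplication argument, not a printed
equation.  A two-mode fit whose mean ratio falls outside [1.5, 2.5] is
flagged `NOT_CONSISTENT_WITH_DUPLICATION` — the split then reflects
something other than simple collapsed duplication.  One known reading
caveat, visible in the bundled demo: in a *male* library a sizeable
X/Y-linked fraction sits at half the autosomal depth and can legitimately
form the lower mode, in which case the "duplication-corrected" size is an
overcount; the per-side coverage statistics in the output make this case
recognisable.

## Pipeline and determinism

`run_pipeline` executes simulate → count → cq → muller → covmix → report.
Every stage writes a provenance record (stage, parameters, seed, version,
input digests) and no output carries a timestamp, so a rerun under the same
configuration is byte-identical — asserted by hashing every output file in
the test suite.  The report refuses to combine outputs whose provenance
seeds disagree.  Stage failures abort with the stage name; the CLI maps
validation errors to exit code 2 and stage failures to 3.

## Problem sizes in the tests

The statistical checks use panels chosen to make their expectations sharp at
desk scale: 10 kb contigs at ≥ 25X yield per-contig CQ noise of ~3–4 %, so
50-contig panel means resolve the 2.0 and 0.0 expectations to well under the
±0.1 band; classification precision/recall is measured over 520 autosomal,
30 X and 20 Y contigs of 5 kb at 25X; mixture recovery uses 20 seeded
simulations of 2,000 contigs with a 0.3 duplicated fraction at 30X; the
oracle-equality suite uses 50 randomized fixtures small enough for exhaustive
scans.  The bundled demo genome has 120 contigs (90 anchored autosomal, 12 X,
8 Y — two with 10 % leak — and 10 collapsed duplications) sequenced at
43X/34X/28X.

## What the synthetic data do not show

The generator draws i.i.d. bases: real genomes contain repeat families,
which multiply EXACT-regime placements and are precisely why the Y band is
0.3 rather than 0; here only `y_leak` mimics that effect in a controlled
way.  Quality scores are constant, errors are substitution-only, there is no
adapter or contaminant material, no within-pool polymorphism, and no
assembly step — contigs are the truth, so passing tests validate the
statistics given an assembly, not the assembly itself.  Conclusions about
real libraries (where trimming, contamination and fragmented assemblies
intervene) inherit all of those caveats.
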