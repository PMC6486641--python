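# Methods

This note documents the models implemented in `hapmet`, the defaults and
why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical and design choices that were genuinely
open.

## Haplotype assignment

Each read is assigned to a parental haplotype from SNPs segregating
between the two strains of an F1 cross. Two evidence streams are scored
identically and then reconciled.

**Score model.** An observed allele with quality *q* is correct with
probability S(q) = 1 − exp(−0.6927 − 0.1203·q). The coefficients are
empirical constants of the basecall-quality scale (S(0) ≈ 0.5: a
zero-quality base is uninformative; S(30) ≈ 0.987). They are exposed in
`PipelineConfig` but not refitted here — the fitting procedure behind
them is not part of this package. Reference-agreeing observations
contribute S, alternate-agreeing ones 1 − S; bases matching neither
allele, and deletions over the SNP, are excluded. The aggregate
h ∈ [0, 1] is the mean contribution over the n informative SNPs, and
H = sgn(h − ½) with sgn(0) = 0 — an exactly balanced read is treated as
uncalled rather than broken by an arbitrary tie rule.

**Signal stream.** Signal-space genotype calls arrive on a shifted
quality scale; q is offset by −35 and floored at 0. The floor is a
deliberate choice: the score model returns values below ½
(anti-informative) for negative arguments, which a correctness score
should not do, so sub-offset calls are uninformative-at-worst instead.

**Combination rules**, applied in order (min_snps = 5, ratio = 3):

1. n_base < 5 and n_signal < 5 → unassigned.
2. H_base = H_signal (both nonzero) → that call. Agreement of two
   uninformative calls (both exactly ½) is not evidence and does not
   satisfy this rule.
3. n_base > 3·n_signal → H_base; (4) symmetric for signal.
5. |h_base − ½| > 3·|h_signal − ½| → H_base; (6) symmetric.
7. otherwise unassigned.

The 3× inequalities are strict, so an exact 3:1 ratio does not decide.
Reads the signal HMM produced no output for have n_signal = 0 and are
resolved by rule 3 from basecalls alone — this is what lets the combined
caller assign strictly more reads than a signal-only method.

## Maternal recombination

When the maternal line carries a second strain one generation back, the
maternal genome is a mosaic. Reads are haplotyped three ways by running
the same scorer against each strain table: a confident alternate call on
the paternal-strain table labels the read paternal (CAST); among the
rest, a confident alternate call on the FVB table labels it FVB, a
confident reference call labels it mm10, and reads under the five-SNP
floor on both tables stay unassigned.

The FVB fraction among maternal reads is computed in 100-kb tiling
windows (reads binned by alignment midpoint; windows without maternal
reads are dropped from the fit and spanned by the surrounding segments).
The window series is fitted with greedy binary recursive partitioning
(CART anova): at each node the best split by within-segment sum of
squares is accepted only if the node holds ≥ minsplit = 5 windows and the
split improves the total fit by more than cp = 0.1 of the root sum of
squares. An absolute guard of 1e-12 on the improvement prevents splits
driven by floating-point noise on constant input. Split coordinates fall
midway between adjacent window starts. Segments with fitted FVB
proportion > 0.5 have their maternal SNP alleles replaced from the FVB
table. The fit is cross-checked in the test suite against both an
exhaustive-split oracle and the R `rpart` implementation.

## Methylation calling

Methylation callers emit, per read and CpG call group, likelihoods
L_M and L_C of the methylated and unmethylated state. CpG sites < 11 bp
apart share overlapping 6-mer contexts and are chained into one call
group (greedy left-to-right chaining, which equals transitive closure for
an interval relation). Bayes' rule with prior p₀ gives

  β = 1 / (1 + ((1 − p₀)/p₀) · L_C/L_M),

computed in log space as a logistic of llr − log((1 − p₀)/p₀), so
|llr| > 700 cannot overflow and ±∞ map exactly to 1/0. The logistic is
evaluated as (1 + tanh(x/2))/2; tanh is odd, so β(llr) + β(−llr) = 1
holds exactly at p₀ = ½. The default p₀ = 0.5 reflects the ~40–55%
global CpG methylation of placental tissue; it is configurable.

Group averages β̄ = (1/n) Σ βᵢⱼ are computed per haplotype (maternal,
paternal, and "all"; unassigned reads contribute only to "all") and per
cross. For per-site comparison with bisulfite data each group is split
back into its member cytosines on both strands (forward C and the
reverse-strand C at position + 1), every site inheriting the group β.
Binary concordance uses a 0.36 threshold for nanopore β and 0.5 for
bisulfite — nanopore group averages are biased toward intermediate
values, which shifts the natural decision boundary below ½. Both
thresholds are parameters.

## Differential methylation

Per call group and haplotype-sample, N is the read count and
X = round(Σ β) the methylated count — rounding the probabilistic mass
rather than thresholding each read preserves information from uncertain
calls (a per-read 0.5 threshold is available as an alternative upstream).
The two-group test follows the published beta-binomial/arcsine design of
DSS without its smoothing mode: with p̃ = (X + ½)/(N + 1) and
Y = arcsin(2p̃ − 1), the coefficient is the difference of group means of
Y and its variance combines per-sample terms Var(Y) ≈ (1 + (N − 1)φ)/N,
the delta-method variance of this transform under beta-binomial counts.
The Wald statistic is referred to a standard normal, two-sided.

Dispersion φ is estimated per site by method of moments on the
within-group residuals of Y (residuals about each group's own mean, so a
genuine group difference does not inflate φ) and shrunk toward the
genome-wide mean with weight n/(n + 4), n the number of covered samples —
with two samples per group the raw estimate has ~2 degrees of freedom and
is unusable alone. Under a null simulation (2 vs 2, N = 10, φ = 0.1) the
test's empirical false-positive rate at nominal 0.05 is ~0.05, which the
acceptance suite checks.

Regions: significant sites (p < 1e-5) with a shared effect sign are
clustered while consecutive significant sites are ≤ 100 bp apart; a
cluster spans first-to-last significant site including interior
non-significant sites, and survives if it holds ≥ 3 sites over ≥ 50 bp
with ≥ 50% of its sites significant. Sign consistency is required of the
significant member sites; interior non-significant sites may fluctuate.
The area statistic is the sum of Wald statistics over all member sites
and regions are ranked genome-wide by its absolute value. All region
parameters are exposed in `DMRParams`. No genome-wide multiplicity
correction is applied beyond the 1e-5 site threshold — the procedure is
deliberately permissive and rank-oriented.

The reciprocal-cross design yields four haplotype-samples; the
parent-of-origin contrast pools maternal alleles of both crosses against
paternal alleles, and the strain contrast pools same-strain alleles
across crosses. A genuine parent-of-origin effect is balanced within each
strain group and therefore invisible to the strain contrast, and vice
versa.

**Power at the 1e-5 site threshold.** The unsmoothed site test cannot
reach p < 1e-5 at low coverage: with 2 samples per group of N = 10 reads
the maximum attainable |Y| difference is ~1.97 (because of the p̃
shrinkage) against a null SE ≥ 0.32, i.e. |Z| ≤ ~4.4 even for a perfect
0-vs-100% difference, while 1e-5 two-sided requires |Z| > 4.42.
Region-level recovery of planted differences of Δp = 0.5 therefore needs
deeper per-sample counts; the power simulations in the test suite and
acceptance script use N = 40 reads per sample with φ = 0.01, chosen by
this a-priori power analysis (per-site noncentrality ≈ 5.4). The
end-to-end synthetic pipeline reports DMR recovery at both 10x (where
recovery is expectedly near zero) and 30x coverage; smoothing across
neighbouring sites, which borrows strength at low coverage, is out of
scope here.

## Visualization smoothing

Per-read tracks are loess-smoothed (degree 1, tricube weights, no
robustness iterations) with span α = 0.1 + 8·10⁻¹¹·(max{10⁵ − L, 0})²,
L the read length: short reads are smoothed hard (α → 0.9), reads ≥
100 kb use the floor 0.1. The span is clamped to at least 2/n so every
local fit sees two points, fits are evaluated at call-group midpoints
(the evaluation grid is otherwise arbitrary), and fitted values are
clipped to [0, 1]. Tracks are emitted as TSV; plotting is left to the
caller.

## Synthetic data

The generator emulates the reciprocal-cross design end to end: a random
reference with planted CpG dinucleotides (background density 0.01/bp;
0.02/bp island-like inside planted DMRs), disjoint CAST-like (1e-3/bp)
and FVB-like (5e-4/bp) SNP tables, log-normal read lengths (mean 15 kb),
10x default coverage, 10% substitution error with Phred qualities that
are exact transforms of the error rate (q = −10·log₁₀ e) so the score
model operates in its calibrated regime, 1% deletions, and an
independent signal stream (80% SNP detection, 5% error, +35 scale).
Methylation truth is bimodal — alternating 50-kb domains at 0.2/0.8,
averaging the tissue-like 50% — with planted DMRs near-complete
(0.95/0.05) as at real imprinting control regions, and per-read group
llrs of ±4 with Gaussian noise (sd 2). Bulk bisulfite calls average the
two alleles at Poisson(30) coverage.

Not emulated: sequence-context-dependent error and methylation-calling
biases, split/chimeric reads, copy-number and structural variation,
mapping bias around SNP-dense regions, and the correlated errors of real
signal-space callers. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated
generative model, not performance on real flow-cell data.

## Degenerate inputs and ties

Empty SNP overlap yields n = 0 evidence, not an error; h is undefined and
the read falls through the rule table to unassigned or the other stream.
Call groups covered by zero reads emit no summary. Sites with an
uncovered group are skipped by the test. Windows without maternal reads
are omitted from the partition fit. Genes on chromosomes without DMRs
receive an infinite distance and are excluded from medians with a
warning. All coordinates are 0-based half-open internally; VCF (1-based)
and the methylation TSV dialect (inclusive end) convert at the I/O
boundary only.

## Known limitations

- The recombination fit reimplements rpart's anova splitting with
  minsplit and cp only (no minbucket, cross-validation pruning or
  surrogate splits).
- The DMR test is a faithful reimplementation of the published two-group
  arcsine/beta-binomial design, not a byte-compatible port of DSS;
  p-values can differ in detail from DSS output.
- Recovering call-group member sites from span endpoints alone (as in
  `compare-rrbs` when only a summary TSV is available) uses the two span
  endpoints as sites; interior CpGs of multi-site groups are only
  recovered when the full site list is known.
- Only CpG-context 5mC is modelled; no 5hmC, no non-CpG contexts.
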