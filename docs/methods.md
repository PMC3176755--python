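# Methods

## The problem setting

Transcriptome profiling of individual plant cell types (e.g. the megaspore
mother cell and the surrounding nucellus of an *Arabidopsis* ovule)
requires laser-assisted microdissection and two rounds of linear RNA
amplification before hybridization to a short-oligo array. Amplification
distorts the intensity distribution enough that the vendor's
mismatch-probe-based present/absent calls become unreliable. The approach
implemented here replaces them with an *empirical* null: probes on the
array that no longer match the current genome annotation ("negative
probes") measure pure background, and probeset-shaped resamples of them
yield a per-array background distribution for probeset-level signals.
Everything downstream — detection calls, enrichment testing, gene-set
analysis, clustering, and the segregation statistics used to characterize
mutant lines — builds on that foundation.

## Probe annotation

Probes are mapped by exact substitution-only Hamming search: each probe is
split into `max_mismatches + 1` disjoint equal-length seeds; any window at
distance ≤ m must contain one seed exactly (pigeonhole), so seed lookup in
a target k-mer index followed by verification finds *every* qualifying
window. No gaps are considered — the contract is Hamming distance, tested
against a naive all-windows oracle. Transcripts are searched sense-strand
only (probes are designed to match the cDNA); genomic targets on both
strands, reverse-strand hits reported at forward-strand coordinates
(0-based, half-open). Non-ACGT characters mismatch everything, including
themselves, and force a brute-force scan for that probe (with a warning).

Probes with perfect hits to more than one gene are removed from their
probesets ("multimap"); probesets left with fewer than `min_probes`
(default 1) probes are removed entirely. The negative pool consists of
probes used by no retained probeset whose best hit anywhere exceeds two
mismatches, or that have no hit within the search cap at all; the
provenance records the best-hit count (`None` for no-hit, flagging that
the true distance is only bounded below by the cap).

## Summarization

**RMA.** Per array, observed intensities are modelled as O = S + B with
S ~ Exp(α) on [0, ∞) and B ~ N(μ, σ²). Conditionally S | O = o is a
normal N(o − μ − σ²α, σ²) truncated at zero, whose mean (computed in log
space for tail stability) is the background-corrected value — strictly
positive and strictly monotone in o, verified against numerical
integration of the posterior. Parameters are estimated per array by a
documented heuristic: μ = kernel-density maximizer over the lower half of
the data, σ = RMS deviation of points below μ, α = reciprocal mean
exceedance above μ; all three are injectable for testing. Quantile
normalization forces every column's sorted values to the across-array mean
of sorted values; ties within a column receive the mean of the reference
values at the tied ranks. Summarization is Tukey median polish on the
log2 probes × arrays block (row sweeps first, tol 0.01, max 10 passes);
the expression value per array is overall + array effect. A vectorized
variant polishes stacks of equally sized pseudo-probesets in lockstep
(per-block convergence) and is bit-identical to the scalar path.

**MBEI.** Per probeset, the multiplicative model PM_ja ≈ φ_j·θ_a is fitted
to quantile-normalized linear-scale intensities by alternating least
squares under Σφ² = J; probes with standardized residuals > 3 are
down-weighted once and the model refitted; log2 θ_a is reported. PM-only —
the data model contains no mismatch probes. Non-convergence after
`max_iter` warns and returns the last iterate.

## Detection calls

Pseudo-probesets (default: 2,000 sets of 11 distinct probes per repeat, 20
repeats) are resampled uniformly from the negative pool — without
replacement within a set, with replacement across sets — and summarized
through the *same* background-correction/normalization pass as real
probesets (one joint normalization; the alternative of a separate pass was
considered and rejected as it would let the pseudo-probesets see a
different background). Per array, a probeset signal x receives
p = (#{null ≥ x} + 1)/(n_sets + 1) per repeat, averaged arithmetically
across repeats. The +1 smoothing keeps p in (0, 1] and makes the call rate
at a threshold t slightly conservative (≈ t − (1 − t)/n_sets); the
measured false-positive rate at t = 0.02 is ≈ 0.0195.

Group calls: an array is "present" when p ≤ 0.02 (inclusive — the
threshold itself is significant); a group of R replicates is **P** when at
least ⌈¾R⌉ arrays are present, else **M** when at least ⌈½R⌉, else **A**.
P and M are disjoint by construction. Venn counts over the present sets of
several groups report every exclusive intersection region.

## Differential enrichment

A per-gene one-way cell-means model with variance pooled across groups
gives means, s² and df = Σ(n_g − 1). The empirical-Bayes prior
(d₀, s₀²) is estimated by moments of log s²: with
e_g = log s²_g − ψ(d/2) + log(d/2), the excess of Var(e) over ψ′(d/2)
equals ψ′(d₀/2), inverted by Newton iteration on the trigamma function;
s₀² follows from the mean. Non-positive excess means the observed spread
is at or below pure sampling noise → d₀ = ∞ (full shrinkage to s₀²) with
a warning. Posterior variances s̃² = (d₀s₀² + d·s²)/(d₀ + d) feed
moderated t (df d₀ + d) and a one-way moderated F.

Selection rules:

* **atlas** — a gene is enriched in the target group when every
  target-vs-other contrast has BH-adjusted p < 0.01 *and* positive log
  fold change. Positivity is required explicitly: "enrichment" means
  up-regulation, not mere difference.
* **gametophyte** — a moderated-F gate at BH FDR < 0.05 first; then, among
  gated genes, per-contrast BH-adjusted p < 0.05 and positive logFC in all
  contrasts. The per-contrast adjustment is computed within the gated
  subset (the gate defines the analysis set); this detail is a design
  choice where the procedure's published description is silent.

Detection-based prefiltering keeps genes with array-level presence in at
least `min_present_arrays` (default 3) of the arrays entering a
comparison. The atlas analysis conventionally runs on MBEI expression and
the gametophyte comparison on RMA expression; both functions accept
either.

## Gene-set and GO enrichment

Family tests are two-sided Fisher's exact tests of the significant set
against the whole array universe; the two-sided p sums hypergeometric
point probabilities ≤ the observed one with a 1 + 1e-7 relative slack for
floating-point ties. GO tests are one-sided (over-representation) on
true-path-propagated annotations (each term inherits all descendants'
genes; cycles are an error). `Expected = annotated·|sig|/|universe|`
exactly. Decorrelation variants:

* **elim** — terms are processed bottom-up by height; a term with
  p < α_elim (default 0.01) has its propagated genes removed from all its
  ancestors before those are tested.
* **weight** — a soft variant of child–parent decorrelation, pinned as
  follows since published implementations differ across versions: terms
  are processed bottom-up; for a node u, each child c with p_c < p_u
  multiplies the weights of c's genes by p_c/p_u in u *and all of u's
  ancestors*, and p_u is recomputed with the new weights (weighted counts
  rounded to integers for the hypergeometric). Child p-values are never
  revised. Consequences used as normative tests: a single-term DAG reduces
  to plain Fisher; disjoint siblings keep their classic p; the parent of a
  more-significant child gets a larger p than classic.

p-values below 1e-30 display as "<1e-30"; the raw value is kept in a
separate column.

## Clustering

Complete linkage over euclidean or manhattan distances, implemented
directly (O(n³), ample at array scale) because the tie-break is part of
the contract: among equally close cluster pairs, the pair whose combined
sorted leaf-index tuple is lexicographically smallest merges first, making
dendrograms reproducible under input permutation. Complete linkage is
inversion-free, so heights are checked non-decreasing. Leaf order puts the
subtree containing the smaller minimum leaf index on the left. Row scaling
uses the population SD (divisor n) — a display convention only; constant
rows map to zero with a warning. The heatmap writer emits both a raster
image and the reordered scaled matrix as TSV (the testable artifact).

## Transmission genetics

TE = 100·n_het/n_wt from a heterozygote × wild-type cross (100% under
Mendelian transmission), displayed at one decimal with half-away-from-zero
rounding; raw values are retained. The 1:1 χ² uses expected = total/2 per
class without continuity correction, significant when X² > 3.85 (df 1,
α 0.05). Phenotype fractions report integer percent with a Wilson 95%
interval. Relative fluorescence divides each nucleus's intensity sum by
the within-ovule minimum (the dimmest nucleus is exactly 1).

## The synthetic-data generator

The generator emulates: per-probe multiplicative affinities (log2-additive,
N(0, 0.5), array-invariant — matching median polish's additive model);
Gaussian optical background on the log2 scale (mean 6 ≈ 2⁶ scanner counts,
SD 0.5 per observation); an intrinsic expression level per gene drawn from
an exponential with rate 0.25 (mean 4 log2 units above background),
*truncated at `max_signal` = 8* so that background + signal stays within a
16-bit scanner's dynamic range — untruncated draws produce physically
impossible intensities (~2³⁰) whose probes monopolize the top quantile
ranks; planted-enriched genes additionally keep headroom
(level ≤ max_signal − effect), because a fold change on a saturated gene
is unmeasurable on a real array as well. Each gene is expressed in a
tissue with probability `expressed_fraction` (default 0.6); planted
enriched genes are expressed in every tissue so their target-vs-rest
contrast equals the planted effect. The intrinsic level is drawn once per
gene and shared across tissues and probes; replicate-to-replicate
variation comes only from the Gaussian background term. Intensities are
assembled on the log2 scale and exponentiated, so RMA's additive
convolution assumption holds only approximately — an intentional
model-mismatch stress.

What the generator does *not* emulate: optical spatial artifacts, batch
effects, probe GC/sequence-dependent affinity structure, mismatch-probe
pairs, amplification-induced 3' bias, or cross-hybridization. Passing
tests therefore demonstrate correctness of the computations and
calibration of the detection statistic under the stated noise model, not
robustness to those real-data pathologies.

Negative probes are random 25-mers accepted only after a brute-force
Hamming scan confirms ≥ 3 mismatches against every window of every target
(both genome strands); placement failure after 1,000 retries per probe is
an explicit error. Multi-mapping probes are created by copying a real
probe's 25-mer into a second gene's transcript. Crosses draw
n_het ~ Binomial(n, p/(1+p)) for transmission probability p.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces every
output byte-for-byte.

## Numerical behaviour worth knowing

* **Quantile normalization attenuates lone extreme-tail effects at small
  scale.** With a few hundred genes, one gene's 11 probes occupy a
  measurable share of the upper tail; forcing sorted columns equal across
  arrays then shrinks that gene's between-group contrast (measured: a +4
  log2 effect reads ≈ +3 at 120 genes when the gene sits alone at the top;
  the attenuation vanishes as the probe universe grows, and is why the
  effect-recovery test uses a mid-distribution, densely surrounded gene).
  Significance-based recovery is unaffected.
* **Background subtraction stretches low-end contrasts.** For genes whose
  expression is close to the optical background, the contrast on the
  estimated signal scale exceeds the observed-scale fold change
  (log2(2^(l+e) − 1) − log2(2^l − 1) > e for small l). This is a property
  of the convolution model, not an artifact.
* Detection p-values never reach 0 (the +1/(n+1) smoothing) and the
  present-call rate at threshold t is ≈ t − (1 − t)/n_sets, i.e. slightly
  conservative.
* The moderated-t limits are exact: d₀ = 0 reproduces the classical pooled
  two-sample t; d₀ = ∞ uses the normal reference distribution.
* Median polish tolerance 0.01 and 10 iterations are fixed conventions;
  degenerate single-probe blocks return the probe values with zero probe
  effect.
* MBEI's scale is fixed by Σφ² = J; θ is clipped to the smallest positive
  float before log2 in pathological all-outlier cases.

## Problem sizes

The test suite works at deliberately small scale: the recovery study uses
500 genes × 11 probes across 8 tissues × 4 replicates with 20 planted
effects of +2 to +4 log2; detection-call calibration uses one array with
1,574 negative probes, 2,000 null sets of 11, 20 repeats, and 10,000 test
probesets; clustering sanity runs 20 reseeds of a 150-gene atlas. These
sizes give stable Monte-Carlo behaviour (3-SE acceptance bands) while
keeping a full run in seconds on one core.

## Known limitations

* The Hamming search deliberately ignores indels; a probe hybridizing
  across a small insertion would be missed where a gapped aligner would
  find it.
* Probes with no hit within the mismatch cap enter the negative pool; if
  their true best distance is exactly 3 this is correct, but a cap below 3
  cannot distinguish "far" from "unknown" — the provenance marks them.
* The `weight` GO variant is a pinned interpretation; other published
  implementations will give different (similarly decorrelated) p-values.
* Group sizes enter moderated t only through 1/n_i + 1/n_j; unequal
  within-group variances are not modelled (no array weights).
* The per-gene shared expression level means the generator has no true
  biological replicate-to-replicate expression variability; detection and
  enrichment power on real data will be lower than on these simulations.
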