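# Methods

This note documents the statistical models behind `kappacascade`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that shape
edge-case behaviour.

## Peak calling

The caller scans each chromosome with a `window_bp` = 200 window at
`step_bp` = 25 (the window size and the four-read/two-per-strand candidacy
rule follow the CisGenome-style convention; the step is a package choice and
is configurable). For every scanned window we compute an upper-tail Poisson
p-value for the total tag count with rate λ = max(global background,
depth-scaled input count in the same window). The global floor — total tags
÷ genome length × window — prevents p = 0 in regions where the input is
empty. Input counts are scaled by the ratio of sample to input total tags.

Benjamini–Hochberg adjustment runs across **all scanned windows**, not only
candidates. This matters: candidacy requires strand balance in addition to a
count threshold, so among candidates the total-count p-values are
conditionally biased low, and adjusting within that selected set rejects
~26 % of candidate windows on pure background. Adjusting across all windows
restores the null (measured false-discovery proportion ≈ 10⁻⁴ on 100
background simulations) without affecting enriched-site recovery.

Windows passing q ≤ `fdr_max` (0.1) and fold enrichment (tag + 1)/(scaled
input + 1) ≥ `min_fold_vs_input` (2) are merged when closer than
`merge_gap_bp` (200). A merged peak inherits the count of its maximum window
(leftmost on ties), the summit is that window's center, and q is the minimum
over constituents. Factor-level fold filters (RelA ≥ 10×, Rel ≥ 5×) exist as
a final step on merged peaks but are **off by default**: the generator's
default 10× site enrichment yields expected peak folds of ≈ enrichment + 1 ≈
11× with σ ≈ 1–2, so a same-magnitude filter removes planted sites
stochastically rather than selecting against noise. On synthetic runs the
caller's default fold ≥ 2 filter carries the specificity; the published-style
10×/5× convention can be enabled via `CascadeParams.factor_fold_filters`.

Replicate-common peaks are pairs overlapping ≥ 1 bp, reported as the union
interval with the pair minimum of count and fold (conservative), re-merged
where union intervals overlap.

## Annotation

Peaks are classified by summit with priority promoter > exon > intron >
intergenic. The promoter window is −1 kb..+100 bp around the TSS in gene
orientation (both bounds inclusive, configurable). Every peak is assigned
the nearest-TSS gene; the distance cap is ∞ by default. Equidistant ties
resolve to the lexicographically smaller gene id so annotation is
deterministic.

## Differential expression

One negative-binomial likelihood-ratio engine serves all contrasts.

*Normalization* is median-of-ratios over genes nonzero in every sample,
rescaled to geometric mean 1; if no such gene exists the code falls back to
library-size factors with a warning. For ATAC window counts the pipeline
instead uses sequencing-depth (total-tag) factors: consensus windows are few
and all signal-carrying, so median-of-ratios over them would absorb the very
accessibility changes under test.

*Dispersion* (α, the NB size-inverse) is a pooled method of moments: within
each replicated group, Var = μ + αμ², giving α̂ = Σ(s² − m) / Σ(m² − s²/n)
per gene — the denominator correction removes the E[m̂²] = m² + Var/n bias,
which otherwise leaves α̂ ~15 % low at n = 2. Raw estimates (kept unclipped;
negative values carry information) are shrunk with weight 0.8 toward the
mean of their log-mean expression bin (20 bins). The heavy shrinkage is
deliberate: with two replicates the raw per-gene estimate has ~8 df, and its
plug-in noise alone inflates LRT type-I error to ~0.075; at weight 0.8 the
measured size is 0.04–0.06 with uniform p-values (the engine is exactly
calibrated when the true α is supplied). The bin *mean* rather than median
is used because the estimator's distribution is right-skewed and its median
is ~10 % biased low.

*Testing* fits per-gene NB log-link GLMs by IRLS with α̂ fixed, under
`~ time + treat + time:treat` and `~ time + treat`; the statistic
2(ℓ_full − ℓ_reduced) is referred to χ² on (n_times − 1)(n_treats − 1) df
(time-vs-intercept when only one condition is present), with BH q-values.
All genes share one design matrix, so the IRLS normal equations are solved
batched across genes; step-halving guards the likelihood ascent, and
non-converged fits are flagged with p = 1 (conservative). All-zero genes are
excluded and flagged. The batched fitter is validated against statsmodels'
`GLM(NegativeBinomial)` coefficient-by-coefficient in the test suite.

*Responsive genes* satisfy interaction FDR ≤ 0.05 **and** a
more-than-twofold change vs 0 h in the control condition at some
post-stimulation time (evaluated at the maximal |log2 fc| over post-0 times;
whether the published rule used a single time or the maximum is not
documented, so the maximum is this package's stated choice). Fold changes
are log2((mean + 1)/(baseline mean + 1)) on normalized counts,
replicate-averaged; the +1 pseudocount makes all-zero genes map to 0.

Note an intrinsic limit: multiplying one library's raw counts by c and
re-normalizing is *not* exactly invariant for a count-level model — the
scaled library genuinely has a smaller shot-noise share — so invariance
holds to ~10⁻² in p, not machine precision.

## Kinetic clustering

Profiles are per-gene log2 fold changes at 1/4/18 h (concatenated
control + perturbed, length 6, for contrast runs), row z-scored;
zero-variance rows are flagged and set to zero. k-means uses correlation
distance d = 1 − Pearson, k-means++-style seeding adapted to that metric,
mean-then-restandardize centroid updates (as MATLAB's 'correlation' option
does), ≤ 300 Lloyd iterations, five restarts with seeds seed + restart
index, best total distance kept. Empty clusters are re-seeded at the point
farthest from its assigned centroid. Defaults: k = 3 for the up- and
down-regulated WT programs separately, k = 6 on concatenated profiles for
contrast runs. A Pearson correlation involving a zero-variance vector is
defined as 0 (distance 1).

Cluster kinetic classes (transient-early: peak at 1 h with the 18 h value
below half the peak; intermediate: peak at 4 h; late: peak at 18 h; mirrored
down classes; otherwise mixed) are assigned from the **mean raw fold
changes** of cluster members, not from z-scored centroids — standardization
erases direction, making "induced from 4 h" and "transiently repressed at
1 h" the same shape. The down classes are named down_transient_early /
down_intermediate / down_late, the exact mirror of the up classes.

## Target classification

The evidence table per responsive gene holds: RelA-1h / Rel-18h binding
(from annotated replicate-common peaks), the WT kinetic class, BAY
suppression (interaction q ≤ 0.05 in the BAY contrast and the BAY |fold
change| at the gene's peak time below half the control value), and per-gene
knockout flags. The knockout flags are purely per-gene: a gene is
RelA-dependent-early when its control 1 h log2 fc ≥ 1, its knockout 1 h fc
is below half of control, and its RelA-contrast interaction q ≤ 0.05
(Rel-dependent-late analogously at 18 h; Rel-de-repressed when the knockout
1 h fc exceeds control by ≥ 0.5, same q gate). Cluster-membership gating was
considered and rejected: correlation distance is scale-free, so a
de-repressed profile (knockout = control + 1) and an unaffected one are
≈ 0.97 correlated and co-cluster, diluting any cluster-mean criterion; the
per-gene interaction test is what makes these calls reproducible.

The decision table: not BAY-suppressed → none; suppressed and bound →
direct, suppressed and unbound → indirect; among direct, transient-early +
RelA-bound + RelA-dependent → RelA-selective, late/intermediate + Rel-bound
+ Rel-dependent → Rel-dependent, neither knockout effect → redundant;
Rel-de-repression adds a rel_repressed tag (a gene may be both
RelA-selective and Rel-repressed; the single `subunit_class` field reports
rel_repressed only when no other subunit class applies).

`classification_report` compares calls with planted truth using a priority
mapping (none → null; down-kinetic responsive → down_regulated; then
indirect / relA_selective / rel_dependent / rel_repressed /
redundant_direct). Planted down-regulated genes are unbound and
BAY-sensitive, so the rubric proper calls them indirect; the kinetic
direction is what distinguishes them, and the report uses it. Genes that
never enter the responsive universe count as null calls, so null
precision/recall are measured over the whole gene set.

## Motifs

PWMs are probability matrices scored as log2-odds against the background
composition, both strands, N scoring 0; a sequence is a hit when its best
window reaches the motif threshold (default 6 bits, configurable — a single
global threshold, unlike HOMER's per-motif thresholds, which is a stated
simplification). Enrichment is a hypergeometric upper tail on
sequences-with-≥ 1-hit with the pooled fg + bg universe, BH across motifs.
Promoter windows are −400..+100 bp around the TSS in gene orientation
(500 bp; truncated-at-chromosome-edge sequences are flagged). Built-in PWMs
(κB consensus GGGRNNYYCC, PU.1/Sfpi1 ETS core, IRF core) ship as JASPAR
text; backgrounds must be user-supplied (a per-sequence shuffle helper is
provided), not auto-matched for GC.

## Synthetic-data generator

The generator emulates the statistical structure the cascade assumes:

- **Genome**: equal-sized gene territories (capacity-checked), 2-kb
  three-exon gene bodies on random strands; one planted site per bound gene
  placed in its promoter (20 %), an intron (40 %) or nearby upstream
  intergenic space (40 %), so nearest-TSS annotation recovers the link.
  Left-over sites attach to null genes (bound but non-responsive, as in real
  data).
- **Tags**: uniform Poisson background; active sites emit extra tags at
  `enrichment_fold` (default 10) × background rate over a 200-bp footprint,
  with canonical ChIP geometry (+ strand tags upstream of center, − strand
  downstream, 50/50) so the strand rule is exercisable. Subunit dynamics:
  RelA sites fully active at 1 h with a 30 % residual at 4 h (the early
  binding wave decays sharply but not to zero; the exact residual is a
  modeling choice, not an inferred value); Rel sites active at 18 h, shared
  sites weakly (30 %) Rel-bound at 1 h. Inputs are background-only; ATAC
  libraries gain accessibility at any active site. The expected site tag
  mass is subtracted from the background budget so E[total tags] equals the
  configured depth.
- **Counts**: NB with dispersion α = 0.05, means = lognormal baseline ×
  2^(planted log2 fc) × a uniform(0.7, 1.3) library factor (to exercise
  normalization). Planted programs: early-transient (1 h peak, 30 % residual
  at 4 h) for RelA-selective, redundant and Rel-repressed genes; late (18 h)
  for Rel-dependent; intermediate (4 h) for indirect; a down program
  mirroring the early classes. BAY zeroes every planted effect; RelA loss
  zeroes RelA-selective induction; Rel loss zeroes Rel-dependent induction
  and raises Rel-repressed genes at 1 h.
- **Effect sizes** (the quantities no published number fixes) were chosen
  once from a power analysis at the fixed study conditions (α = 0.05, two
  replicates): the sampling sd of a per-gene interaction log2 fc is
  √(4α/n_rep)/ln 2 ≈ 0.45, so planted contrasts must be ≳ 2 log2 units to
  separate at FDR 0.05. Defaults: induction amplitude 2.5 log2 (≈ 6×,
  typical of strong NF-κB targets) and +2.0 log2 de-repression.
- **RNG**: every stage draws from `np.random.default_rng([seed, stage_code,
  ...])` — genome 11, tags 13 (+ factor code, time, replicate), counts 17 —
  so libraries are independent but fully reproducible, and the same seed
  yields bit-identical datasets.

What the generator does **not** emulate: sequence content (no motifs under
peaks, no GC bias), fragment-length structure (tags are 5′ positions only),
overlapping or nested genes, mappability gaps, batch effects, or
count-mean-dependent dispersion trends. Passing tests therefore demonstrate
that the inference chain is correct and calibrated under its stated model,
not that it is robust to every artifact of real libraries.

## Problem sizes

Defaults keep every check fast on one CPU: the default dataset is 200 genes
/ 100 sites on 4 Mb at 10⁵ tags/Mb; calibration runs use 2,000 genes;
background FDR runs 100 × 1 Mb; the end-to-end recovery run uses 5,000
genes (200 RelA-selective, 300 Rel-dependent, 200 Rel-repressed, 400
indirect, 300 down-regulated, 3,600 null) with 900 sites on 40 Mb. The full
test suite runs in ~25 s and `scripts/acceptance.py` in ~15 s.

## Known limitations

- The qPCR fold-change helper implements the printed ΔCt formula
  (2^(CT(neg) − CT(target))); it is a convenience, not an efficiency-corrected
  quantification.
- The motif module's single score threshold and shipped three-PWM library
  are minimal; users with real data should supply JASPAR matrices.
- The dispersion estimator targets the two-replicate regime; with many
  replicates its strong trend shrinkage is more conservative than necessary.
- Peak summits are window centers, not tag-density modes; sub-window summit
  resolution is limited to step size.
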