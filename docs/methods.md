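# Methods

## Generative model

The synthetic cohort emulates a block-design associative-learning
experiment.  The paradigm alternates Encoding, Rest, Retrieval and Rest
epochs of 27 s at TR = 3 s over 8 cycles (288 volumes, 9 per epoch); cycles
1–4 form the Early phase (linear learning regime), cycles 5–8 the Late
phase (asymptotic regime).  The schedule builder accepts any TR, epoch
length (an integer multiple of TR) and even cycle count, so minimal designs
can be constructed for testing.

Within each epoch the 6-node network signal follows a first-order vector
autoregression

    Z_t = c + B Z_{t−1} + ε_t,   ε_t ~ N(0, σ² I)

where `B[i, j]` is the lag-1 influence of node j on node i.  Every coupling
matrix must be stable (spectral radius < 1); the first volume of each epoch
is drawn from the process's stationary distribution (mean `(I−B)⁻¹c`,
covariance from the discrete Lyapunov equation), so epochs are exchangeable
and no dependence crosses an epoch boundary.  This matches the estimator,
which never forms lag pairs across boundaries; cross-epoch dynamics at
TR = 3 s with intervening Rest would carry no usable information anyway.

**Default coupling.** Diagonal 0.3 everywhere, innovation SD 1.0, zero
intercept (signal level is arbitrary because the estimator includes an
intercept).  In each condition × phase cell a small edge set differs
between groups, with strong coupling 0.35 vs weak 0.05: Early Encoding has
six reduced-in-SCZ frontal–hippocampal–fusiform edges; Late Encoding three
reduced edges toward the dlPFC; Early Retrieval three increased edges
around the dACC; Late Retrieval one increased edge toward and two reduced
edges from the dlPFC.  Rest epochs use weak diagonal-only coupling (0.2)
and are excluded from the dFC analysis.  These magnitudes were chosen once
as a realistic regime: the implied per-subject coefficient sampling error
(~0.16 at 32 effective observations per cell) makes the 0.30 group gap
detectable but not trivial at n = 24 vs 31.

**Covariates.** Age and FSIQ are Gaussian per group (HC: 28 ± 7 years,
101.29 ± 10.55; SCZ: 29 ± 8 years, 87.74 ± 6.06); the antipsychotic dosage
ratio PDD/DDD is log-normal (median 1, log-SD 0.5), patients only.
Covariates are generated independently of coupling unless an explicit edge
link is configured; a link adds `slope · z` to the chosen edge's coupling,
with z the standardized covariate clipped to ±3 so per-subject matrices
stay stable at realistic slopes (they are re-validated regardless).

**Behavior.** Per subject, Gompertz parameters (a, b, c) are drawn around
group means — defaults HC (0.90, 1.0, 0.9), SCZ (0.75, 1.2, 0.6), SDs
(0.08, 0.3, 0.15) — giving patients a lower asymptote and a later
inflection; the block-t recall count is Binomial(9, a·exp(−exp(b − c·t))),
or the rounded noise-free value in `noise="none"` mode.

**Seeding.** One master seed; per-subject streams are spawned from a
`SeedSequence`, so cohorts are bit-reproducible and adding subjects does
not perturb earlier ones.

## Estimation

**Segmentation** extracts contiguous volume runs per (condition, phase),
optionally shifted forward by a hemodynamic offset (default 0; the BOLD
delay is roughly uniform across a 27 s epoch, and any choice shortens
segments).  Segments shorter than p + 2 are dropped with a warning.

**MVAR.** Per target node, OLS on lagged predictors pooled over segments
(the first p volumes of each segment are predictors only); intercept
included by default, per-segment demeaning available.  Standard errors come
from the standard OLS covariance, t = estimate / SE.  Model order defaults
to p = 1 — at TR = 3 s longer lags carry little directed information —
but arbitrary p is supported (order selection is out of scope).  The edge
panel records, per subject, the 30 off-diagonal lag-1 coefficients in a
stable ordering (row-major by target, then source; columns named
`source->target`).

Two modes exist.  *Bivariate* (default): one 2-node model per node pair,
both direction coefficients taken from the same fit — this mirrors the
classical pairwise Granger analysis of small task networks.  *Multivariate*:
one 6-node model per subject.  The estimands differ: the pairwise
coefficient for j→i absorbs influences routed through omitted nodes, so a
group difference on one edge can surface on neighboring edges that share a
node ("leakage"); the multivariate coefficient conditions on all other
nodes and coincides with the generative coupling.  The worked example shows
this concretely — in Early Encoding the bivariate analysis flags the six
planted edges plus `dlPFC->ITG`, a leakage edge.

**Gompertz fitting.** Bounded trust-region least squares
(a ∈ [0, 1.05], b ∈ [−10, 10], c ∈ [0, 10]) with multi-start
initialization: a data-driven start (a₀ = max fraction; b₀, c₀ from a
log-log linearization), the best point of a deterministic coarse grid scan
over the bound box (a basin locator), and jittered variants.  The best
converged solution is kept; all-zero data short-circuits to a degenerate
a = 0 fit.  Reported quantities are the raw (a, b, c) of the formula plus
the derived inflection time b/c, covering both labeling conventions in use
for this curve.  Note the estimator's sampling distribution for a is
right-skewed for low-capacity learners under binomial(9) noise with 8
blocks (a minority of fits sit at the upper bound), so the *mean* fitted
asymptote of a low group carries an upward bias of roughly +0.08; an
independent grid-search oracle exhibits the same bias on identical data.
Group-mean curve values outside [0, 1] are rejected at generation time.

**Mixed ANOVA.** Classical split-plot sums of squares with observation
weighting (valid for unequal group sizes with one between factor): group is
tested against subjects-within-group, time and group × time against the
within-subject residual; partial η² = SS_effect / (SS_effect + SS_error).
No sphericity correction by default.  Results were cross-checked against an
independent implementation on balanced and unbalanced designs.  Group
contrasts on fitted parameters use Welch t with pooled-SD Cohen's d;
subjects whose fit failed are excluded and counted.

## Inference

Edge-wise group comparison: Welch (unequal-variance) t per edge — robust to
the 24 vs 31 imbalance — with Benjamini–Hochberg step-up adjustment across
the 30-edge family of each condition × phase cell (four separate families,
matching the per-cell presentation of such analyses; a single global family
across all 120 tests is available via `inference.family = "global"`).
Edges with zero variance in both groups get p = 1 and a degenerate flag.
The direction label is a pure function of the sign of the HC − SCZ mean
difference.

Covariate regressions are Pearson correlations (equivalent to the simple
regression slope test) per edge, BH-adjusted within (condition, phase,
covariate); dosage runs within the patient group only, age and FSIQ across
all subjects; missing covariates are excluded listwise with counts
recorded.  Behavioral covariate tests correlate each covariate with Early
and Late mean recall and the fitted curve parameters.

## Calibration results the tests compute

- OLS, ANOVA, Pearson and BH outputs equal independent brute-force oracles
  (normal equations, explicit sums of squares, closed-form r, exhaustive
  step-up cutoff search) to ≤ 1e-8 on randomized small instances.
- VAR(1) coefficients are recovered within ±0.05 at 2000 volumes.
- The per-coefficient t test's null rejection rate lies in the 99% binomial
  band of 5% over 2000 replicates (two independent AR(1) series of 200
  volumes each; critical value from the t distribution at the fit's
  residual degrees of freedom).
- Over 500 replicate cohorts with 6 truly different and 24 null edges, the
  mean realized false discovery proportion of the edge-wise comparison is
  ~0.04, within the BH target (0.05 · 24/30 = 0.04) plus Monte-Carlo error.
  This study estimates in multivariate mode, where generative-null edges
  are null in the estimand; under bivariate estimation the same study
  measures the leakage phenomenon described above rather than the FDR
  step's calibration.

Problem sizes for these studies (500 cohorts, 2000 null replicates, series
lengths 200–2000) were chosen as the smallest at which the Monte-Carlo
error is comfortably below the margins being tested.

## What the generator does not emulate

The simulated signal is the VAR process itself: there is no hemodynamic
convolution (an optional exponential-smoothing stress filter is the only
concession), no physiological noise, motion, drift or spatial structure,
and ROI extraction is exercised only on constructed sphere fixtures.
Passing tests therefore demonstrate correctness of the estimators and of
the inference calibration *given* lag-1 linear dynamics — they do not
establish that pairwise MVAR coefficients on real BOLD data identify
neuronal directionality (hemodynamic variability across regions is the
classical objection).  The behavioral generator assumes a shared curve
family and independent binomial noise across blocks; real recall data show
serial dependencies it does not model.

## Known limitations

- Bivariate-mode estimands include indirect influence (see leakage above);
  treat edge-level discoveries as pairwise-predictive, not structural.
- No model-order selection, spectral Granger measures, sliding-window
  estimation, permutation inference or network-based statistics.
- The mixed ANOVA offers no Greenhouse–Geisser correction yet; with 8
  blocks and compound-symmetric simulated noise this is benign, but real
  data may need it.
- 4D image support is limited to sphere-average extraction with voxel
  membership by world-coordinate distance; no partial-volume weighting.
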