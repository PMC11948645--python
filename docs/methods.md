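# Methods

This note documents the models, numerical choices and the synthetic
cohort generator behind `gradnorm`, including what the generator does and
does not emulate — and therefore what passing tests do and do not show
about real data.

## Gradient estimation

Subject connectivity is handled in Fisher-z space. For gradient
estimation each row of the z-matrix keeps its strongest 10% of
off-diagonal entries ranked by **signed** value (ties broken by ascending
column index, so results are bit-reproducible); an absolute-value ranking
is available behind `use_abs`. Profile similarity uses the normalized
angle kernel `1 - arccos(cos(r_i, r_j))/pi`. Diffusion map embedding uses
the Fokker–Planck convention (`alpha = 0.5`), a dense symmetric
eigensolver on the conjugated Markov operator (exactness over speed; the
intended regime is P ≤ ~1000 parcels), drops the trivial constant
eigenvector, and scales component j by `lambda_j / (1 - lambda_j)`
(diffusion time 0). Eigenvalue gaps below 1e-10 are flagged as degenerate.
Component signs are deterministic (largest-magnitude loading positive);
after template alignment, signs follow the template, whose first
component is oriented so DMN parcels load positively.

The template is always computed from the **group-mean connectivity
matrix**, never from averaged embeddings. Individual embeddings are
aligned by orthogonal Procrustes rotation without scaling (a with-scaling
variant exists behind a flag). Ten components are estimated by default;
only the first two are consumed downstream.

For the binary topology graph the threshold is **global**: the strongest
10% of all positive edges (upper triangle) are retained and symmetrized.
A per-row rule would break the symmetry the participation coefficient
assumes on an undirected graph.

## Normative models

The response distribution is the sinh-arcsinh family in its original
parameterization, `F(y) = Phi(sinh(tau * asinh((y - mu)/sigma) - nu))`,
which is Gaussian at `nu = 0, tau = 1`. The location gets an intercept, a
cubic P-spline in age (10 interior knots, second-order difference
penalty) and a sex-indicator-weighted copy of the same basis (a
varying-coefficient sex deviation); log-scale gets an intercept plus the
age spline; skewness and tail weight are constants. The skewness constant
uses a log link by default — matching how the model family is usually
printed in normative-modeling work — which restricts skew to be positive;
an identity link is available (`nu_link="identity"`) and is the right
choice when features are left-skewed.

Fitting maximizes the penalized likelihood blockwise (mu block, sigma
block, (nu, tau) block; L-BFGS-B inner steps with analytic gradients),
capped at 20 sweeps, followed by a joint L-BFGS-B polish over the full
parameter vector. The polish matters: with weak penalties, pure blockwise
alternation zigzags between strongly coupled blocks and can fail to reach
the tolerance in hundreds of sweeps, while the joint step converges
immediately from the blockwise warm start. The response is standardized
internally before fitting and the coefficients mapped back afterwards, so
a fixed smoothing weight means the same thing regardless of the feature's
units and centile scores are exactly equivariant under affine transforms
of the data. Smoothing weights default to 1.0 and can be selected by
generalized AIC (penalty multiplier 3) on the grid {0.1, 1, 10, 100};
trajectory fits in the pipeline use the GAIC selection because peak-age
extraction is sensitive to spline wobble in sparsely sampled age regions.
Spline bases evaluate out-of-range ages at the nearest boundary and
scoring emits an extrapolation warning.

Transfer recalibration re-estimates only the mu and log-sigma intercepts
by maximum likelihood (Nelder–Mead on the two scalars), freezing every
age-dependent term — the standard intercept-recalibration recipe for
porting a reference-cohort model to a new site or study.

### Likelihood-ratio tests on smooth terms

The age-effect test (is the location age smooth needed?) and the
sigma-trend test (does the scale change with age?) are computed from
**near-unpenalized** maximum-likelihood refits, with degrees of freedom
equal to the column rank of the dropped smooth block and a Bartlett-type
`(n - p)/n` correction on the statistic. We first implemented the test on
the penalized fits with effective-df reference distributions
(`tr(H)`, `2tr(H) - tr(H^2)`, Satterthwaite moment matching); all
variants over-rejected materially under the null (empirical size 0.08 to
0.12 at alpha = 0.05, n = 500), because the unpenalized-likelihood gain of
a weakly penalized 14-column smooth behaves like the full-rank chi-square
while effective-df references undershoot it. The corrected classical LR
test has empirical size ~0.04–0.05 over 500 null replicates and retains
full power against planted smooth effects. The tests refuse to run when
`n < p_full + 10` — an unpenalized refit below that is meaningless.

## Hierarchy score and group analyses

The hierarchy score is the cosine similarity between a subject's aligned
G1 map and the vector of per-parcel normative medians (not means) at the
subject's age and sex. Group trajectories reuse the normative machinery on
the score; the reported "slope per year" is the mean finite-difference
derivative of the median curve over the fitted range (per sex; pointwise
derivatives are available from the fit object), and a peak age is
reported only when the curve's maximum lies at least 0.5 y inside the age
range. Group comparisons of centiles use Welch's unequal-variance t with
Benjamini–Hochberg correction (implemented in-house, cross-checked
against statsmodels in the tests); the network level averages each
subject's centiles within network first. Developmental stages are
half-open bins [5, 12), [12, 15), [15, 22], with boundary ages belonging
to the older bin.

## Topology and mediation

The participation coefficient follows the standard definition on the
binary graph; isolated nodes get PC = 0 with a warning. PC normative
centiles can be fitted within any cohort; the function's `fit_mask`
argument restricts fitting to a reference subset while scoring everyone.
The pipeline fits PC models on the study's TD group and scores both
groups against them. Scoring each group against its own group's model is
also supported (call the function per group), but it absorbs the group
mean into that group's own normative trajectory, which regresses away
exactly the diagnosis-related variance a downstream mediation needs — so
the pipeline deliberately uses the reference-scored convention.

Mediation is the standardized three-regression decomposition (a, b, c,
c', indirect = a·b; the linear identity c = c' + a·b holds to machine
precision) with a subject-level percentile bootstrap (5,000 resamples by
default; resamples that collapse the group indicator are redrawn and
counted). Two pipeline-level choices matter:

* **Age is partialled out** of x, m and y within every stage cell. The
  stages are up to seven years wide; residual within-bin age trends in
  both the mediator and the outcome otherwise masquerade as mediation.
* The mediator entering the regressions is the **deviation z-score**
  (probit of the centile). Centiles compress extreme deviations against
  the (0, 1) ceiling, which specifically attenuates the
  mediator-outcome covariance of the most deviant — i.e. the planted —
  network; the probit is monotone with the centile but linear in
  deviation units.

Note the percentile bootstrap CI of a product is conservative at the
complete null (both paths zero): its empirical coverage is above the
nominal 95%, the textbook behavior of the product bootstrap. A
bias-corrected variant is not implemented.

## The synthetic cohort generator

The generator writes connectivity directly in Fisher-z space as a
weighted sum of (a) a rank-1 term `outer(s·g, s·g)` around the subject's
gradient axis, (b) within-network module blocks with per-subject,
per-network strength jitter, (c) sparse subject-specific strong
"hub" edges, and (d) symmetric Gaussian noise; `simulate_timeseries`
inverts to correlation space (tanh), enforces positive definiteness by
the smallest sufficient convex shrinkage toward the identity, and samples
Gaussian series whose empirical correlation converges to the target.
Everything is deterministic given (parameters, seed); per-subject
randomness derives from a stable hash of the subject id.

Planted conditions (defaults):

* the axis `g0` places the seven networks from Visual (−1.2) to DMN
  (+1.2) with a small within-network spread; its expression grows
  linearly with age in TD (`s(age) = 1 + 0.04(age − 5)`);
* the ASD group carries a global inverted-U attenuation of the axis
  peaking (at exactly 1.0) at 15 y, with a steeper post-peak branch;
  childhood compression of somatomotor/attention loadings toward zero
  (sqrt-shaped ramp vanishing at 15 y, so the group trajectory rises
  identifiably into its peak) and a mild persistent DMN compression;
* from 16 y a latent "integration" factor u (ASD-shifted half-normal)
  removes within-DMN connectivity from half the DMN parcels, compresses
  the DMN loadings further (lowering the hierarchy score), and the freed
  global edge quota is absorbed by strengthening sensory within-module
  edges — positions where extra edges leave the sensory networks' own
  participation essentially flat;
* symptom scores are Gaussian-copula-correlated (default rho = −0.4)
  with the planted alignment, with five noisy subscores.

Generator parameters were chosen once to encode these stated conditions
and are documented here as the study conditions the tests exercise.

### What the generator does not emulate, and a structural limitation

No hemodynamics, motion, scanner or site artifacts (site offsets exist as
an optional additive constant only), no spatial autocorrelation beyond
the network blocks, no second-gradient (G2) planted structure, and no
skewed real-world age pyramids unless the "skewed" sampling option is
chosen. Passing tests therefore demonstrate that the estimation machinery
recovers planted effects through the full pipeline — not that real
cohorts behave like the generator.

Two findings from building the generator are worth recording. First,
after row-thresholding, a rank-1-plus-blocks z-matrix yields an affinity
whose leading diffusion component is a monotone but *stepwise* warp of
the planted axis: Pearson correlation between the recovered template
gradient and `g0` plateaus around 0.95–0.97 regardless of mixture
weights. The generator's documented recoverability guarantees are
therefore |r| ≥ 0.95 for the template and |r| ≥ 0.9 per subject — not
arbitrarily close to 1.

Second, *network-exclusive mediation is not a well-posed target under a
globally thresholded graph.* The binary topology graph retains a fixed
quota of edges, so any latent that raises DMN participation necessarily
reallocates retained edges to other networks, making several networks'
PC co-move with the latent; and subject noise realizations alone induce a
within-group covariance between some networks' PC and the hierarchy score
(both derive from the same matrix). Wherever a group PC shift exists —
unavoidable wherever gradient deviations are planted — these covariances
produce nonzero indirect effects beyond the planted DMN/oldest-bin cell.
In the demo cohort the planted cell is the strongest network mediator in
its bin and the early bins are largely clean, but strict exclusivity
("no other significant network-bin cell") is not robustly achievable, and
the corresponding end-to-end test documents this by failing on exactly
that clause.

## Problem sizes

Defaults used by the shipped analyses: demo cohort with 200 parcels, 300
subjects per diagnostic group plus a 300-subject TD reference cohort;
tiny fixture with 21 parcels and 25 per group; statistical calibration at
n = 500 with 200 replicates; mediation bootstraps 5,000 (pipeline
default) or 2,000 (demo checks). These sizes were chosen so a full
analysis completes in minutes on a single CPU while leaving all planted
effects comfortably detectable.
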