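# Methods

## Detection-time statistics

Each round of the detection game yields a time-to-first-correct-click for
one butterfly image against one background, right-censored at the
timeout (10 s by default): detection failures enter every statistic at
exactly 10 s, the convention for this design. Rows with times above the
timeout, non-positive times, unknown sides/outcomes or missing fields are
rejected with a recorded reason, never clamped.

Players whose total found-count across all their games is below three are
removed entirely (the assumption being that they did not understand the
task). The threshold is strict — exactly three finds is kept — and the
count is per *player*, not per game, because the exclusion targets
responders. Replay learning is quantified by a REML random-intercept
model `time ~ game_number + (1 | player)` over players with at least two
games, with the game number assigned by order of first appearance in the
log; its marginal R² is fixed-effect variance over fixed + intercept +
residual variance.

For each image the mean detection time is computed against every
background; the background with the longest mean is that image's *most
cryptic background* and its mean time is the image's detectability score
(rationale: cryptic species are expected to be optimised for specific
backgrounds, conspicuous species to stand out on most). Ties are broken
by the lexicographically smallest background id so results are
deterministic. The dorsal–ventral statistic takes, per background shown
for both sides, `d_b = mean_ventral(b) − mean_dorsal(b)`; because "the
absolute mean of the time difference" admits two readings, both
`|mean_b(d_b)|` (default, `abs_of_mean`) and `mean_b(|d_b|)`
(`mean_of_abs`) are implemented behind a flag. Differences are computed
only over backgrounds observed for both sides, since random image
assignment leaves unequal coverage and a paired comparison requires
pairing.

Species without a dorsal image get the across-species mean imputed before
z-scoring, which places them at (numerically exact) zero after
standardisation so they do not pull on slope estimates; the same rule is
applied to the difference statistic. z-scores use the sample (n−1)
standard deviation. Dimorphic species contribute one row to the
species-level predictor table, averaging over their dorsal morphotypes;
per-morphotype scores remain available for figure-style tables.

## Phylogenetic correlation

Under Brownian motion the trait covariance of two tips equals the depth
of their most recent common ancestor, so for an ultrametric tree the
correlation is shared depth over tree depth; non-ultrametric input is
normalised per pair by `sqrt(depth_i × depth_j)`. Shared depths are
computed from root-to-tip and patristic distances (dendropy), which is
exact and O(S²). Tips are matched to study species only through an
explicit user-supplied mapping table — the code never guesses taxonomy —
and pruning preserves path lengths while suppressing degree-2 nodes.
Eigenvalues in (−1e−8, 0) are treated as numerical noise: clipped at
1e−10, the matrix reconstructed and re-normalised to unit diagonal;
larger violations are errors. Dimorphic morphotypes share one tip and
one species-level random effect.

## The toxicity model and its sampler

Per assay `deaths ~ Binomial(n, p)` with
`logit(p) = x'β + u_species`, `u ~ MVN(0, σ²C)`. Model 1's design is
[1, z(dorsal cryptic time), z(ventral cryptic time)]; Model 2's is
[1, z(difference statistic)]. The response stays per-assay; species mean
mortalities are reporting conveniences only. Predictor collinearity is
reported as a variance-inflation warning above 2 and never silently
resolved. β has flat improper priors (a normal prior of configurable SD
is available, used e.g. for calibration experiments); σ has a
half-Student-t prior with df 3 and scale 2.5 — the conventional
multilevel default — both exposed. Overdispersion beyond the binomial is
deliberately not modelled.

Sampling is adaptive Metropolis-within-Gibbs on the non-centered scale
`u = σ L z` with L the Cholesky factor of C. Three move families are
composed per sweep:

1. per-coordinate random-walk updates of β, log σ and z, with proposal
   scales adapted toward 44% acceptance in batches of 25 iterations
   during warmup and frozen afterwards (log-σ carries its Jacobian);
2. *translation* moves that shift β_j and compensate u so the linear
   predictor — hence the likelihood — is unchanged and only the prior on
   z decides acceptance (valid because the design is constant within
   species); these break the strong β/u posterior ridge;
3. a *scale* move multiplying σ by e^δ and z by e^−δ (u unchanged), with
   the deterministic map's log-Jacobian −Sδ in the ratio; this breaks
   the σ/‖z‖ ridge that funnels centered samplers.

The linear predictor is maintained incrementally per coordinate and all
chains advance simultaneously in vectorised numpy, so a 61-species fit of
4 chains × 3000 iterations takes seconds. Defaults are 4 chains × 2000
iterations with the first half as warmup; draws are reproducible given a
seed, and R̂ above 1.01 triggers a warning. Setting the phylogenetic SD
to zero collapses the model to ordinary logistic regression (used as a
cross-check against IRLS); prior-only sampling is available for
verifying the σ marginal.

Validation, all in the test suite: the joint log-density matches an
independent scipy-composed reference to 1e−8; the no-phylogeny limit
matches an IRLS logistic fit within Monte-Carlo error; with C = I the
posterior means of β match an independently coded Laplace-grid
approximation; prior-only σ draws pass a Kolmogorov–Smirnov test against
the half-t; and simulation-based calibration on a 20-species × 4-assay
design yields uniform rank statistics for β and σ. Diagnostics (split
rank-normalised R̂, bulk and tail ESS) are computed by arviz.

## Variance decomposition

Bayes R² follows the residual-draw definition on the count scale: per
draw, fitted counts `ŷ = n·inv-logit(η)` and residuals `y − ŷ` give
`R² = Var(ŷ)/(Var(ŷ)+Var(e))`, summarised over draws; a latent-scale
variant is behind a flag. The marginal (fixed-effect) R² uses the
latent-logit decomposition `Var(x'β) / (Var(x'β) + σ² + π²/3)` per draw,
with π²/3 the logit distribution-specific variance; the analogous ratio
with σ² in the numerator is reported as the phylogenetic share (and "the
remaining variation" is reported as this share, not as the difference of
the two R² values — both are printed). Variances are over design rows
with the sample (n−1) divisor. Genus effects are means over member
species of the posterior-mean random effects, ranked.

## What the synthetic generator emulates — and what it does not

The generator's defaults are the study conditions: 61 species on a
pure-birth ultrametric tree, 30 backgrounds = 30 rounds per game (each
background exactly once per game, random order), ~1700 players × 2 games,
10-s censoring, 120 images (59 dorsal + 61 ventral; three dimorphic
species with two dorsal morphs, five species with no dorsal image), 3–13
assays of 10 Daphnia per species, water/methanol controls (18 assays
each) and cricket/cockroach controls (10 each) at death probability
0.005 — the order of observed control mortality, not a fitted value.
True coefficients default to the fitted model's scale (β0 = −1.18,
β_dorsal = −0.21, β_ventral = −0.06, β_diff = −0.27 log-odds per SD) and
σ_phylo to 1.

Detection times are log-normal around a latent per-image × background
mean — the standard right-skewed reaction-time family; the study itself
implies no particular distribution, so this is a modelling choice, with
`detection_noise` (log-scale SD, default 0.35) controlling dispersion and
the mean parametrised so that zero noise reproduces the latent mean
exactly. Per-image conspicuousness levels span near-immediate detection
to close to the ceiling, matching the observed spread of detection
times. One designated background per image has its latent mean inflated
2 s above that image's maximum, so the true most-cryptic background is
known for oracle tests; a configurable fraction of other backgrounds gets
a milder +1 s inflation. A small fraction of "non-compliant" players
(default 3%) find fewer than three butterflies, exercising the QC filter.
A weak replay-learning slope (−0.006 s/game) is injected.

Not emulated: player drop-out mid-game (simulated games are complete, so
found-per-game runs higher than in real logs), screen/device effects,
spatial click coordinates, UV reflectance and predator visual systems,
and any image-content-driven saliency — detection means are latent
parameters, not pixel-derived. Passing tests therefore certify the
statistical machinery, not the realism of any particular biological
effect size.

## Problem sizes and known limitations

The test suite runs scaled-down designs chosen to keep the full suite in
the minutes range: 12-species studies for pipeline round-trips, a
60-species × 7-assay design over 20 replicate studies for parameter
recovery, 20 species × 4 assays for simulation-based calibration, and
single fits of 2–4 chains × 400–3000 iterations. The acceptance script
runs the full 61-species design.

Known limitations: with ~60 species under deep phylogenetic correlation,
σ is weakly identified — the data carry far fewer than 60 independent
observations of the species effect — so its posterior leans on the
half-t prior, and frequentist-style interval coverage at a fixed true σ
can fall below nominal even though the posterior itself is correct
(cross-checked against an independent non-centered JAGS fit and a
Laplace-grid oracle) and prior-matched calibration is clean. β estimates
are essentially unbiased in the same experiments. The marginal-R²
estimator is one of several published variants; its absolute value is
not comparable across variant choices, so the variant used (latent
logit, π²/3) is stated in the report output. Censoring at 10 s
compresses differences among highly cryptic images, and detectability
scores estimated from finite rounds carry sampling noise that mildly
attenuates slopes when assays are generated from latent rather than
pipeline-computed scores.
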