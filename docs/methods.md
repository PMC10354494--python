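# Methods

`colonynet` quantifies whether groups of social animals differ *consistently*
in their emergent network structure, over and above what external conditions
explain.  Its model system is a multi-colony aviary study of zebra finches:
individually barcoded birds filmed at perches and feeding tables, one frame
every few seconds, over replicated colonies, years and seasons.  This note
documents the models and conventions behind each stage, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Daily network construction

Two daily networks are built per colony from the per-frame detections:

* **Interaction networks** (social + copulation perches).  Two birds "clump"
  in a frame when their barcode pixel positions on the same perch camera are
  strictly less than 80 px apart (about one body width).  The edge weight is
  the *strict simple ratio index*: frames clumped divided by frames both
  birds were detected on the same perch camera.  Restricting the denominator
  to co-present frames isolates the decision to interact from the tendency
  to be in the same place.
* **Association networks** (feeding tables).  Edge weight is the simple
  ratio index: frames both birds were on the same feeding table divided by
  frames at least one of the two was detected at any table
  (gambit-of-the-group).

Conventions where the definitions leave room:

* "Same perch" means same camera in the same frame; perch cameras are pooled
  into a single dyadic denominator.
* A dyad with an empty denominator gets weight 0 (no data = no edge), so
  every adjacency matrix is total.
* Binary edges exist wherever the weight is strictly positive.
* Node sets are per context: a bird never seen at a feeder that day is not a
  node of that day's association network.

Both constructions are validated against frame-by-frame brute-force
enumeration on randomized fixtures (exact equality, including crowded frames
with several birds per camera).

## Colony-level metrics

Seven metrics per daily network, three social scales:

| scale | metric | definition |
|---|---|---|
| local | mean weighted degree | mean row sum of the weight matrix |
| local | mean binary degree | mean count of nonzero edges per bird |
| local | mean edge weight | mean over all N(N−1)/2 dyads, zeros included |
| intermediate | CV edge weight | per-bird sd/mean of its N−1 weights, averaged over birds |
| intermediate | edge density | nonzero dyads / (N(N−1)/2) |
| global | mean path length | mean shortest-path distance, largest component |
| global | diameter | max shortest-path distance, largest component |

Numerical conventions: standard deviations use the n−1 denominator; birds
whose weights are all zero have an undefined CV and are excluded from the
average (a `global` CV over all dyads is available as a toggle); shortest
paths treat edge weights as traversal costs, the behaviour of common graph
libraries when handed a weight attribute on these data.  Because a weight is
a rate in [0, 1], "distance" here is small between strongly bonded birds'
neighbours; the common alternative cost 1/weight is exposed as
`weight_mode="inverse"`.  Path computations use Dijkstra on a sparse matrix
(scipy.sparse.csgraph); independent Floyd–Warshall and networkx
implementations serve as test oracles.

### Correction for disconnected networks

Global metrics are undefined across disconnected components.  The correction:
compute the metric on the largest connected component (*value 2*); then,
100 times, join all clusters (isolated detected birds count as clusters of
size one) with edges carrying the smallest strictly positive edge weight
observed anywhere in the study for that network type, sampling one
representative per cluster, and compute the metric on the joined network
(*value 1*); the corrected value is value 2 plus the mean of
(value 1 − value 2).  A connected network is returned unchanged, exactly.

Open points resolved here: with three or more clusters the join topology is a
random chain over the clusters (the minimal augmentation; a star topology is
a toggle), and value 1 is computed on the fully joined network.  Mean path
length averages unordered pairs (equivalent to ordered for undirected
graphs).  The repetition count (default 100) and the RNG seed are explicit
parameters; corrected values are deterministic given a seed.

## External drivers and model table

Per colony-day drivers: group size (birds present), group composition (age,
1 vs 2 years), daily mean temperature, daily mean humidity, daily cloud
cover (okta, 0–8), aviary aspect (northeast/southwest), aviary floor area
(12 vs 24 m²), and observation effort — the daily number of camera
detections for the camera system matching the network type under analysis
(perch detections for interaction networks, feeder detections for
association networks; which system the effort covariate should track was
left open by the source description, and tying it to the analysed network
type is the choice made here).

Missing humidity values are imputed with the same-year mean of the observed
values; only missing cells are touched.  Numeric drivers are centred and
scaled to unit sd *within each analysis subset* (network type × season),
since the seasons are analysed as independent replicates; scaling parameters
are retained so partial-residual plots can be drawn on the raw driver scale.
Factors are 0/1 indicators with reference levels northeast, 12 m² and
1 year.  A driver that is constant within a subset (e.g. group size in a
study without removals) carries no information there and is dropped from
that subset's models with a warning.

## Variance partitioning

Per metric × network type × season, two Gaussian linear mixed models:

* **uninformed**: metric ~ 1 + (1 | colony)
* **informed**: metric ~ drivers + (1 | colony) + (1 | date), colonies and
  dates crossed.

Estimation is restricted maximum likelihood (REML) — a deterministic,
dependency-light substitute for the Bayesian posterior machinery often used
for such models; the derived quantities are estimator-agnostic functions of
the variance components.  Crossed models are fitted with statsmodels
`MixedLM` variance components (agreement with lme4 is enforced by a test).
Single-random-effect models use an exact profiled-REML solver (the
restricted likelihood is optimized in the single variance ratio, with
Woodbury identities making each evaluation O(n)); it reaches the same
optimum as `MixedLM` — enforced by tests — at ~10× less cost, which the
bootstrap experiments need.  Variance components are truncated at zero and
boundary hits are flagged; non-convergence is flagged, never silent.

Derived quantities:

* **Repeatability** `R = σ²_colony / (σ²_colony + σ²_date + σ²_resid)` —
  the adjusted ICC: the fixed-effect variance is excluded from the
  denominator, so R answers "of the variance not already attributed to the
  drivers, how much is consistent colony identity?".  The unadjusted form
  (fixed-effect variance in the denominator) is a toggle, since the source
  analysis does not print its formula.
* **Marginal/conditional R²**: `RM2 = σ²_fixed / σ²_total`,
  `RC2 = (σ²_fixed + σ²_colony + σ²_date) / σ²_total`, with `σ²_fixed` the
  sample variance of the fixed-effect linear predictor.
* **VIF** per fixed effect from the fixed-effects-only design, `1/(1−R²_j)`.
* **Partial residuals** ("corrected metrics"): response minus all non-focal
  fixed-effect contributions and the predicted random effects, leaving
  intercept + focal term + residual.

### Bootstrap confidence intervals

95% intervals are the 2.5/97.5 percentiles of R over 1000 (default)
bootstrap refits.  The default is a **parametric** bootstrap: each replicate
simulates new colony effects, date effects and residuals from the fitted
components and refits.  A nonparametric alternative resampling colony-day
rows within colonies is provided (`method="rows"`), but it conditions on the
realized colony effects; with 12 colonies the between-colony sampling noise
dominates the uncertainty in R, and in a calibration experiment (true
R = 0.5, 12 colonies × 15 days, B = 200, 200 replicate experiments) the row
bootstrap covered the truth in only ~52% of experiments versus ~90% for the
parametric bootstrap, which is why the latter is the default.

## Synthetic data generator

The generator's defaults encode the reference study design: 3 years ×
4 colonies × 28 birds, 10 pre-breeding days, 14/10/28 post-breeding days
(82 study days, 328 colony-days, 656 potential daily networks).  Latent
sociality is additive on the log-odds scale: clumping probability for dyad
(i, j) of colony c on date d, *given co-presence*, is
inv-logit(α + u_c + v_d + g_i + g_j + p_ij + Σβ_k x_k) with independent
Gaussian colony, date, individual and dyad effects (defaults
σ = 0.6/0.3/0.25/0.4; the source reports no latent-scale effect sizes, so
these are illustrative, chosen to put clumping rates and repeatabilities in
a realistic mid range).  Weather is shared by colonies observed on the same
date; temperature is seasonal (uniform 0–16 °C pre-breeding, 10–25.6 °C
post-breeding), humidity uniform on 48.1–92.7%, cloud uniform on 0–8 okta —
the observed ranges of the reference study.  Aviary area doubles after year
one; ages alternate 1/2/1 years; one humidity day is missing by default;
birds leave permanently with a small per-day removal probability (0.002),
reproducing the 22–28 group-size range.

Perch co-presence is a **dyadic encounter process**: each camera-frame holds
at most one uniformly sampled pair (probability 0.5), a single bird (0.2) or
nothing.  This is a deliberate simplification of birds free-mixing on a
perch: if many birds shared a camera frame, no assignment of pixel positions
could give every dyad an independent clumping indicator (clumping would be
transitive in position space), whereas the encounter process keeps each
dyad's conditional clumping probability *exactly* the inverse-logit above,
making the construction stage verifiable against the generator analytically.
Clumped pairs are written < 80 px apart (|Δx| uniform on [0, 79]),
co-present non-clumped pairs in [80, 2000], so the one-body-width rule is
exactly recoverable.  Feeder detections come from a parallel bout process
(each bird joins a bout per frame with inv-logit probability of a similar
predictor, default intercept −2).  Every record survives independently with
a per-colony-day detection rate drawn from (0.6, 1.0) — the observation-
effort driver.  A single integer seed drives everything through
deterministic sub-stream derivation.

What the generator does *not* emulate: spatial structure beyond the 80-px
rule, temporal autocorrelation within a day, bout dynamics at perches,
breeding behaviour, or detection biases correlated with identity or weather.
Passing tests therefore establish that the pipeline recovers the structure
it assumes — not that real colonies satisfy those assumptions.

## Problem sizes of the shipped experiments

The default generator runs 2000 frames per camera per day (keeping per-dyad
sampling above the ~20 observations-per-dyad guideline for robust networks).
The study-accounting runs in the tests and the acceptance script use a
reduced stream (120–150 frames/day): network *counts* are invariant to the
frame budget.  Calibration experiments: parameter recovery uses 12 colonies
× 30 days × 20 replicate studies per true R ∈ {0, 0.25, 0.5, 0.75};
bootstrap coverage uses 200 experiments at B = 200 (true R = 0.5,
12 colonies × 15 days).

## Known limitations

* REML point estimates replace posterior distributions; credible intervals
  of the original workflow are not reproduced, only bootstrap intervals.
* With 12 colonies, variance-component estimates are noisy and R intervals
  are wide; boundary estimates (σ²_colony = 0) occur at low true R.
* The parametric bootstrap inherits the Gaussian model; heavy-tailed metric
  distributions would call for a cluster bootstrap over colonies, which the
  12-colony design makes coarse.
* The informed model treats drivers as exogenous; observation effort is
  partially endogenous to sociality in the generator (more co-presence,
  more detections), as it plausibly is in real data.
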