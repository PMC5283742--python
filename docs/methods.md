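# Methods

This note records the models, parameter choices and numerical conventions
behind `pitchnet`, and what the synthetic-data validation does and does not
establish about real tracking data.

## Passing networks and centralities

The network of one team is the directed integer adjacency `A[v, w]` =
successful passes v→w over the 10 outfield players (goalkeepers are
excluded everywhere). Two count→length conventions are provided because
notational studies rarely state one:

* `reciprocal` (default): `len(v, w) = 1 / A[v, w]`, no edge ⇒ ∞. More
  passes ⇒ shorter, so closeness rewards strong links. Under this
  convention scaling all counts by k multiplies closeness by k and leaves
  betweenness unchanged (unit-tested).
* `hop`: every existing edge has length 1 (unweighted replication).

The path census runs Dijkstra per source and counts geodesics by summing
predecessor counts over tight relaxations; two path lengths are considered
tied when they agree to a **relative tolerance of 1e-12** (reciprocal
lengths are ratios of small integers, so genuine ties are exact in IEEE
arithmetic far above this tolerance, while accumulated rounding sits far
below it). Closeness sums distances over *reachable* targets only and
reports the reachable count — with infinite farness a single isolated
receiver would zero every score on weakly connected match networks. A node
reaching no one scores 0. Betweenness excludes endpoints (`s ≠ v ≠ t`) and
is left unnormalized. Both centralities are verified against exhaustive
simple-path enumeration on random digraphs and against an independent
Brandes implementation.

## Approximate entropy

The classical estimator with self-matches,
`ApEn = Φ^m(r) − Φ^{m+1}(r)`, `Φ^m(r) = (N−m+1)^{-1} Σ_i ln C_i^m(r)`,
is computed with Chebyshev template distances (chunked, so memory stays
bounded for long series). Defaults `m = 2`, `r = 0.2·SD` follow the
movement-science convention; both are configurable and echoed in output
metadata. Because r scales with the series SD, ApEn is invariant under
affine rescaling of the input (tested). Constant series return exactly 0;
fewer than m+2 samples raise. The often-quoted 0–2 output range is an
empirical observation for this parameterization, not a bound, and is not
enforced.

Dyad series are computed per period and ApEn is averaged across periods
with sample-size weights, avoiding the artificial half-time discontinuity;
whole-match concatenation is available. Missing samples are removed, not
interpolated; dyads with fewer than 100 valid samples are flagged
low-confidence.

## Voronoi dominant regions

Both teams' 20 outfield players share one tessellation — a dominant region
is meaningless within one team alone. Cells come from GEOS
(`shapely.voronoi_polygons`) clipped to the pitch rectangle, so per-frame
areas sum to the pitch area to float precision (asserted at rel. err
< 1e-6). Exactly coincident points receive a deterministic ~1e-6 m
golden-angle jitter keyed to player index. Cell areas are validated
against a nearest-site rasterization oracle; note that such an oracle has
a per-cell quantization error of order perimeter × grid step, which caps
how finely a coarse raster can resolve very small cells. The per-player
CV uses the sample SD (ddof = 1), the convention under which two frames
with areas 100 and 200 m² give CV = 47.1%.

## Regularity clustering

The 45 dyad ApEn values are fitted with 1-D Gaussian mixtures by EM for
k = 1…5; k is selected by BIC (a replication flag can force k = 3).
Initialisation combines a deterministic quantile start with 20 seeded
random restarts; the best likelihood wins. A variance floor
`reg_covar = 1e-3 · var(data)` blocks the classic EM singularity
(a component collapsing onto near-coincident points would otherwise
inflate the likelihood past the BIC penalty and over-select k) without
constraining genuine within-class spread. Components are relabelled by
ascending mean: lowest ApEn = "higher" regularity, then "medium" /
"lower"; with k = 2 the labels are higher/lower, with k = 1 "uniform".
All-identical inputs short-circuit to a single class with a warning.

## Statistical layer

* **Standardized difference**: `d = (mean_B − mean_A)/s_pooled` with the
  df-weighted pooled variance; 90% limits via the large-sample normal
  approximation `SE(d) = sqrt(1/n_A + 1/n_B + d²/(2(n_A+n_B)))` (the
  noncentral-t inversion differs negligibly at these n). Bands:
  |d| ≤ 0.2 trivial, ≤ 0.6 small, ≤ 1.2 moderate, ≤ 2.0 large, else very
  large; a value exactly at a threshold takes the lower band.
* **Percent difference** (count-type measures): analysed on the natural
  log scale, back-transformed; the ± limit is the back-transformed
  half-width of the pooled two-sample t interval. Requires strictly
  positive data; zeros route to the plain standardized difference.
* **MBI**: probabilities that the true effect exceeds +SWD, lies within
  ±SWD or falls below −SWD from the t (or normal) distribution of the
  estimate, SWD = 0.2 standardized units. Labels: possible (25–75%),
  likely (75–95%), very likely (95–99%), most likely (>99%); "unclear"
  whenever the 90% CI spans both +SWD and −SWD (the standard non-clinical
  convention). The three probabilities sum to 1 (tested to 1e-9).
* **Correlation**: Pearson r on complete pairs, Fisher-z 90% interval
  (`z ± 1.645/sqrt(n−3)`); bands 0.1/0.3/0.5/0.7/0.9; "unclear" when the
  interval spans both signs. For r = −0.44 with n = 90 the interval is
  [−0.571, −0.288]; reported correlation intervals of this size in the
  literature round to [−0.57…−0.58, −0.29], consistent with n ≈ 90
  directed dyads — an observation, not an asserted equality.
* **Efficacy**: goals·100/shots, one decimal.
* Between-team bases: closeness/betweenness use the 10 per-player scores
  per team as groups; passes use counts over six equal match segments
  (configurable) to obtain a within-match variance; shots exist only as
  match totals, so they are compared with a Poisson-variance standardized
  difference (`(b−a)/sqrt((a+b)/2)`, SE √2 by the delta method) plus the
  log-ratio percent difference. Teams are ranked higher/lower performance
  by shots, then efficacy; exact ties are flagged, not resolved.

## Synthetic match generator

The generator supplies study-like inputs with controllable structure; it
does not model tactics, opponents or ball physics.

* **Movement**: player i follows a discretised OU process with relaxation
  τ = 3 s toward `anchor_i + c_i·(ball − pitch_centre)`, stationary jitter
  SD `noise_sd_m` (default 1.5 m), clamped to the pitch. Ball-coupling
  gains c are role-graded (defenders 0.08–0.10, midfielders 0.18–0.22,
  forwards 0.30–0.32): a *shared* gain would cancel out of every dyad
  difference, leaving no smooth component in dyad distances. The ball is
  an independent slower OU (τ = 9 s, SD ≈ 30×20 m) around the centre.
  Raising `noise_sd_m` shifts dyad-distance variance from the smooth
  ball-driven component to the faster jitter, so mean dyad ApEn increases
  monotonically with it (tested over seeds).
* **Defaults as study conditions**: 106×65 m pitch, 5 Hz, 2×25 min,
  1-4-3-3 with 10 outfield roles, 400 successful passes per team —
  a realistic match-scale pass volume.
* **Passes**: `simulate_passes` draws a chain (each receiver becomes the
  next passer) from a row-stochastic transition matrix; uniform and hub
  topologies are built in. Event times are uniform over the match — the
  downstream metrics never consume pass times, so timing realism is not
  required.
* **Planted correlation**: per-player noise SDs are drawn log-uniformly
  (×1/4…×4 around `noise_sd_m`), spreading dyad ApEn widely. The dyad
  regularity score `s_ij = (σ_i² + σ_j²)/((c_i − c_j)²·var_ball + v₀)` —
  the fast/slow variance ratio — predicts measured ApEn with r ≈ 0.9.
  Rank-normal scores of s are coupled to a Gaussian latent with
  coefficient `planted_rho` inflated by the analytic multinomial
  attenuation factor, mapped affinely to propensities (affine maps
  preserve Pearson correlation) and realised as one multinomial over the
  90 directed dyads, expanded to uniformly-timed events. The planting is
  exact in expectation only: the residual nonlinearity of the score→ApEn
  map attenuates recovery slightly (mean recovered r ≈ −0.34 for a
  planted −0.4 at the problem sizes below). Fixtures can only plant
  non-positive correlations, matching the phenomenon they emulate.
* **Shots/goals**: shots uniform 6–18 per team, goals binomial with
  scoring probability 0.15 (goals ≤ shots by construction), typical of
  youth match score lines.

## What the synthetic validation shows — and does not

Passing tests establish that the estimators are computed correctly (oracle
agreement), that the pipeline conserves its invariants, and that planted
structure (hub centralization, regularity classes, negative
pass-regularity correlation) is recovered at realistic sample sizes. They
do **not** establish that real teams exhibit such structure: the generator
has stationary anchors, no opponent interaction, no possession phases, and
its dyad distances are far better behaved than real ones (no device
dropout beyond what is simulated, no projection artefacts).

## Problem sizes and runtime choices

ApEn is O(N²) in series length, so the test-suite and acceptance runs use
scaled matches (1–2 periods of 1–5 min at 5 Hz, i.e. 300–3000 samples per
player) while the generator's defaults stay at the full 2×25 min; at full
scale a 45-dyad ApEn pass takes a few minutes and is intended for real
analyses. Voronoi summaries default to a 1 s frame stride. Recovery
studies use 40–100 simulated matches; oracle comparisons use 50–200
random instances.

## Known limitations

* The two-step clustering of commercial statistics packages is emulated
  by a BIC-selected Gaussian mixture, not reproduced tree-for-tree.
* The MBI probabilities use the t/normal approximation of the estimate,
  not the original spreadsheet's internals; methods are echoed in output
  metadata.
* The equirectangular projection (mean-Earth-radius degree length) is
  pitch-scale only; it degrades above ~60° latitude and rejects |lat| > 89°.
* Between-team count comparisons from a single match have no natural
  variance basis; the segment/Poisson choices above are documented
  stand-ins, configurable by the caller.
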