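# Methods

`turtlehab` re-implements a telemetry-based habitat-suitability workflow for
foraging marine turtles as a tested, reusable pipeline, and ships a synthetic
study generator with a known ground truth so every stage can be verified by
parameter recovery instead of against unavailable field data.

## Pipeline overview

1. **Synthetic scenes and telemetry** (`synthetic_data`) — seeded coastal
   scenes (land mask, static predictor rasters, dated dynamic stacks),
   habitat-biased true tracks, and realistic telemetry degradation.
2. **Track QC** (`track_qc`) — duplicate/empty-row removal, ARGOS class
   filtering, 24-h burn-in, speed/turning-angle spike removal, land filtering,
   72-h gap splitting, >20-fix segment retention, migration truncation.
3. **Regularization** (`regularize`) — continuous-time correlated random walk
   (CTCRW) fit per track by maximum likelihood through a Kalman filter;
   RTS-smoothed positions on a 12/24/48-h grid with standard errors.
4. **Pseudo-absences** (`pseudo_absence`) — correlated random walks that
   resample each track's empirical step lengths and turning angles, with land
   rejection; 9 simulations per presence track by default.
5. **Annotation and screening** (`env_annotate`) — space-time sampling of
   every predictor at each labelled point, temporal clipping to environmental
   coverage, a 70% pairwise-correlation screen, and Bhattacharyya
   environmental-separation scores.
6. **Modelling** (`brt_engine`) — from-scratch boosted regression trees on the
   Bernoulli deviance with monotone constraints, bagging, relative influence,
   partial dependence, two-way interaction scores, stratified five-fold
   cross-validation, fold-wise pruning, and OOB tree-count selection.
7. **Evaluation** (`evaluation`) — rank-based AUC, TSS/TPR at a 0.5 threshold
   (max-TSS reported as a secondary value), percent Bernoulli deviance
   explained.
8. **Mapping** (`habitat_map`) — per-pixel prediction on the scene grid,
   the strict >0.5 "more likely than not" suitability threshold, area sums,
   zone-overlap shares, and two-date change reports.

`pipeline.run_study(seed)` chains all stages with every random draw derived
from one seed.

## The movement and observation model

Tracks are regularized with a CTCRW: per axis, position/velocity `(p, v)`
with `dv = -beta v dt + sigma dW`. `beta` (1/h) is the velocity
autocorrelation decay, `sigma` (m/h^1.5) the velocity diffusion; axes are
independent with shared parameters (symmetric spatial error). Observation
error is isotropic Gaussian per location class: Fastloc GPS is scaled so the
mean radial error is 40 m (per-axis sd 40/sqrt(pi/2) ~ 31.9 m); ARGOS
classes 3/2/1 use 250/500/1500 m mean radial error, classes 0/A/B
(4/8/12 km) are generated by the simulator but removed by QC.

The published workflow this mirrors used a time-varying move-persistence
state-space model chosen by visual diagnostics. Two deliberate deviations:

- **Constant-parameter CTCRW instead of time-varying move persistence.** The
  state-space model's role here is error correction and regularization, not
  behavioural inference; the CTCRW does that job with an exact
  finite-dimensional Gaussian oracle (the test suite checks the smoother
  against a dense joint-Gaussian conditional to 1e-6).
- **Automated diagnostics instead of visual checks.** A timestep (tried in
  order 12 → 24 → 48 h) is accepted when: per-axis |lag-1 autocorrelation| of
  standardized innovations < 0.3; the median observation interval does not
  exceed the timestep (a finer grid would manufacture positions from the
  prior rather than the data); no estimate sits further than 5 one-step
  process SDs from both temporal neighbours; and the heading circular
  variance is at least 0.01 (rejecting degenerate straight lines or perfect
  loops). Tracks passing no candidate are discarded, with the reason logged.
  All thresholds are config-exposed (`DiagnosticsConfig`).

Optimization is bounded L-BFGS-B on (log beta, log sigma) from three
deterministic restarts; convergence requires an interior optimum with
projected gradient norm < 1e-4 of the mean per-observation negative
log-likelihood. Fits with fewer than 10 usable fixes are flagged
non-converged and excluded.

## The spike filter

The published QC delegated speed/angle filtering to an external data-driven
filter without printing its algorithm. The concrete rule here, using the
same thresholds (9.9 km/h maximum speed, 90 degree inner angle): iterate to a
fixed point the removal of (a) any interior fix whose legs in and out both
exceed the maximum speed — endpoints are judged on their single leg only
once no interior spike remains, since an interior spike explains its
neighbours' fast legs — then (b) any interior fix forming an inner angle
sharper than the threshold with both adjacent legs above half the maximum
speed. An independent O(n^2) re-implementation in the tests confirms the
fixed point. This is documented as an approximation to the published filter,
not a re-implementation of it.

Strict readings used throughout: gaps split tracks only when strictly more
than 72 h; segments are kept only with strictly more than 20 fixes; pairs are
screened only when strictly more than 70% correlated; pixels are suitable
only when strictly above probability 0.5.

Migration removal truncates rather than discarding animals (config
`migration_mode` also offers `drop_track`): the departure onset is the last
fix within 10 km of the pre-departure centroid before displacement first
exceeds 150 km; if the animal returns within the home radius the loop alone
is excised and the remainder re-split, so a post-return residency survives
only if it independently satisfies the gap and minimum-length rules. The
automated onset rule is a proxy for what was originally a visual judgement,
and is flagged as such in the provenance log.

## Boosted regression trees

Stagewise gradient boosting on the Bernoulli deviance, matching the
reference hyper-parameters: tree complexity 5 (five best-first splits, at
most six terminal nodes), learning rate 0.005, up to 10,000 trees (capped at
2,000 in the synthetic study for runtime), bag fraction 0.75 drawn without
replacement, five-fold stratified cross-validation. Terminal values are
Newton steps `sum(y - p) / sum(p(1-p))` shrunk by the learning rate.
Deterministic given the config seed.

Monotone constraints act twice: during the split scan, candidate thresholds
whose child mean residuals violate the sign are rejected; after leaf values
are assigned, values are clipped within bound intervals propagated through
constrained splits (the midpoint of the child subtree means). The second
step makes ensemble monotonicity a guarantee asserted on partial-dependence
grids, not a tendency. Categorical predictors split by exhaustive subset
search up to cardinality 8, above that by ordering categories on their
within-node mean response; unseen codes at prediction time follow the
majority branch.

Relative influence is each predictor's share of total squared-error split
gain, normalised to 100. Partial dependence is the mean logit prediction
with the target column overridden; trees that never split on the target are
evaluated once (an exact shortcut, asserted equal to the literal override
loop to 1e-9). Interaction strength is the residual variance of the two-way
PD surface around its additive (row + column means) part, scaled by the
surface variance, on 20-quantile knots.

Fold-wise pruning drops a predictor only when its influence is at or below
the fold's 10th-percentile cutoff in **every** fold, applied as a single
pass followed by one re-run of cross-validation. OOB tree selection smooths
the per-iteration out-of-bag deviance improvements with a 50-iteration
moving average, takes each fold's argmax of the cumulative sum, and returns
the maximum over folds so the final 100%-data refit encompasses every
fold's optimum ("encompass" read as max; a rounded consensus was the other
candidate reading). Class imbalance (~9:1 absence:presence) is left
unweighted. Fold assignment is row-level stratified by label; an animal-level
option exists because rows within one animal are autocorrelated.

## The synthetic study and what it can show

The generator emulates the structure of an inshore tracking study without
mimicking any real geography:

- **Scene** (default 128x128 pixels of 500 m): connected landmass along the
  west edge with a smoothed coastline; offshore reef patches at roughly one
  patch per 800 pixels (a reef-studded shelf); numerous coastal facilities
  and river mouths (their density scales with coastline length, as on a
  settled coast); static layers (distance to reef/coast/facility/river,
  seagrass probability, categorical geohabitat) and dynamic stacks
  (temperature 18–32 °C, salinity 25–36 PSU, current speed) as band-limited
  space-time Gaussian random fields on a 10-day date axis, each field
  evolving on its own space/time scale (temperature fastest and
  finest-grained, salinity slowest and broadest). Nuisance layers are driven
  by their own random fields rather than by the truth drivers, and are
  fine-grained enough that they cannot act as accidental proxies for the
  handful of track clusters, so influence ranking on this scene is
  identifiable.
- **Truth**: logistic suitability driven by distance-to-reef (exponential
  decay, scale 800 m, height 7) and salinity (Gaussian optimum 31 PSU,
  sd 1.0, height 8) over intercept -12 — effectively reef structure AND
  favourable water, with open water essentially unusable. Because the biased
  walk's stationary density is proportional to suitability, this
  concentrates animals on reefs sitting in good water, the way strong
  foraging-site fidelity behaves; which reefs are good changes slowly with
  the salinity field.
- **Movement**: biased correlated random walk at a fixed 2-h true interval —
  gamma step lengths (mean 500 m/step, ~6 km/day), wrapped-Cauchy turning
  angles (rho 0.7), candidates rejected on land and accepted with probability
  equal to the candidate's suitability.
- **Degradation**: random thinning to 65% retention, per-class positional
  noise, 2% exact duplicates, 0.5% empty rows, 80% of animals carrying GPS
  tags (the rest ARGOS with a class mix), and optional >150 km directed
  departure segments for flagged animals.

The reference study conditions (`pipeline.StudyConfig`) are 15 animals
tracked for 600 true fixes (~50 days), 9 pseudo-absence simulations per
track, and the reference hyper-parameters with the tree budget capped at
2,000; replicate (multi-seed) checks use an 800-tree budget, where the
influence ranking has already stabilised. These sizes keep a full study in
minutes on one CPU while leaving roughly ten thousand labelled rows.

What passing tests show: the pipeline recovers the truth predictors as the
top-ranked influences and separates presences from pseudo-absences with
held-out AUC ≈ 0.9 under known, realistic degradation. What they do not
show: performance on real tag data with tides, duty cycles, behavioural
states, reprojection error, or environmental layers at mismatched
resolutions — none of which the generator emulates. Absolute metric values
on synthetic scenes should not be compared with field studies.

## Numerical and convention details

- Scenes are planar (metres); speeds and distances are Euclidean. Geographic
  (degree) inputs use haversine distances, selected by a CRS flag.
- Pixel containment is half-open: a coordinate on a boundary belongs to the
  pixel above/right of it; zone assignment uses pixel centres, first listed
  zone wins, bias at most one pixel width.
- Dynamic sampling uses the nearest date not after the point's timestamp
  (model outputs are step-valid forward in time); annual layers match by
  calendar year; points before coverage are missing, never extrapolated.
- The correlation screen resolves the worst offending pair first and drops
  the member with the larger mean absolute correlation to all others, ties
  to the later column; the full matrix and drop list are reported for audit.
  Whether the original study screened on presences only is unstated; all
  rows are used here.
- Bhattacharyya coefficients use 100 equal-width bins over the pooled range
  (config-exposed; the original binning is unstated).
- Deviance-explained uses the evaluation subset's own label mean as the null
  model; scores at exactly 0 or 1 are clipped to 1e-12 with a warning.
- Missing predictor rows are dropped before modelling, with counts logged.
- All seeds derive from a single study seed via `numpy` seed sequences;
  every stage is bit-reproducible given its seed.

## Known limitations

- The CTCRW has constant parameters per track; behavioural switching (e.g.
  transit vs forage) is absorbed into a single persistence scale.
- Pseudo-absence steps and angles are resampled independently; joint
  resampling is available as a config option but not the default.
- The land mask stands in for the high-tide line; no tidal stage modelling.
- The migration-onset rule is an automated proxy for a visual judgement.
- Influence rankings for weak secondary drivers are intrinsically noisy at
  small numbers of animals: rows within a track are autocorrelated, so the
  effective sample size is closer to the number of tracks than the number
  of rows.
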