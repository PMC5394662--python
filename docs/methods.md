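# Methods

`psforage` analyses producer–scrounger dynamics in wild birds foraging at
automated, RFID-logged devices: puzzle-boxes that record who opened the
door and who exploited the open door, and open feeders that record
flocking. This note documents the models, the synthetic-data generator,
the numerical choices, and what the test suite does and does not
establish.

## The door automaton

A puzzle-box door opens when a bird performs the solving action
(`opened = 1` in the log) and closes one second after the bird leaves the
perch. Classification replays that physics deterministically over the
visit stream of one device, sorted by arrival:

* `SOLVE` — a visit flagged `opened = 1` at a closed door; starts a
  *solve chain* at position 0.
* `SCROUNGE` — a bird not yet rewarded in the open chain arriving within
  `window_s` (default 1.0 s) of the previous rewarded bird's departure;
  each scrounge restarts the countdown. The door shuts on detection of
  the third scrounger, so a chain holds at most three scrounges.
* `REVISIT` — a bird already rewarded in the open chain returning within
  the window. Revisits are not rewarded and do not extend the window
  (the countdown runs from the last *rewarded* departure). How the
  original firmware logged such returns is not documented; this is our
  convention and it is flagged as such.
* `CONTACT` — any visit to a closed door.

Window comparisons are inclusive (`<=`) on the 1/16-s scanner grid; two
birds in the same tick resolve by file order. A visit flagged `opened = 1`
while the door is already open is logically inconsistent (possible in
real data); it is logged and treated as a scrounge if within the window.

Derived per-bird quantities: *time of first contact* — active-time
seconds from the experiment start to the first detection of any kind;
*latency to learn* — summed closed-door (`CONTACT`) durations before the
first solve, undefined for never-solvers. Active time counts only
06:00–18:00 on weekdays, the availability window of the boxes; weekends
and nights do not accrue. All headline models are restricted to birds
with ≥ 50 rewarded visits (inclusive).

## Gathering events and networks

Feeder detections (visit-interval midpoints) within one feeder-day are
modelled as a 1-D Gaussian mixture over time. The component count is
selected by BIC over 1..`max_components` (default ⌈n/5⌉ capped at 25),
with k-means initialization (5 restarts, fixed sub-seed) and a 1 s²
covariance floor. Because BIC on small samples occasionally ties between
k and k+1 within noise, the smallest k within 6 BIC units of the minimum
is chosen (the "positive evidence" threshold on the Kass–Raftery scale);
genuine splits win by hundreds of units, so the margin only suppresses
spurious ones. Each detection joins its maximum-responsibility component;
components become gathering events; members are the distinct birds
assigned. Fitting per feeder-day keeps the date × location strata intact
for the permutation null.

Associations use the simple ratio index, the Jaccard index of two birds'
event sets: 0 = never in the same group, 1 = always. Node metrics:
strength (row sum of associations), unweighted degree (count of nonzero
associations), betweenness (unnormalized shortest-path count on the
binarized graph — any nonzero association is an edge, tied shortest
paths split a pair's count evenly; the field definition is a path count,
not a weighted variant), and average attended group size (self
included).

## The stratified permutation null

Significance of network metrics cannot come from Wald tests — scores of
birds sharing a network are not independent. The null swaps individuals
between gathering events within date × location strata: a 2×2
checkerboard submatrix (1,0;0,1) flips to (0,1;1,0), preserving every
event's size and every bird's sighting count within each stratum. Swaps
accumulate serially; after each recorded step the metric is recomputed
and the model refitted, giving a null distribution of the coefficient.
Significance uses the 95%-range rule (observed outside the null's
[2.5%, 97.5%] quantiles), accompanied by an empirical two-sided p-value
(1 + #{|null − mean| ≥ |obs − mean|}) / (n_perm + 1) so borderline cases
are quantifiable.

Two numerical points matter here.

*Mixing.* Consecutive states of a serial chain differ by at most one
swap, so with one attempt per recorded step the null coefficients are
strongly autocorrelated and their quantiles understate the true null
spread — in calibration runs this inflated the type-I rate to ~0.33.
Recorded samples must be spaced by enough attempts to decorrelate; the
default is ⌈(number of 1s in the GBI)/10⌉ attempts per step after a
1000-attempt burn-in, which restores the nominal 5% rate. Both knobs are
arguments.

*What the null can detect.* The margins the swaps preserve include each
bird's sighting count, so an association between the trait and *how
often* a bird is seen is invisible to this test by construction. Only
structure in *which* events a bird occupies (e.g. scroungers sitting in
the larger gatherings) is testable. The power simulations therefore tie
the trait to event-size occupancy, not to sighting frequency.

## Tactic trajectories and clustering

For each bird passing the visit filter, the cumulative scrounge
proportion (scrounges / rewarded visits) is evaluated at the end of
consecutive 2-h active-time bins counted from its own first rewarded
event. Trajectories are aligned to equal length by truncation to the
shortest included bird (padding with the last value is available as
`align="pad"`); k-means with Euclidean distance, 10 restarts and a fixed
seed clusters them, with k = 2 for the headline producer/scrounger
split. Cluster means are reported as the mean final-bin proportion
(ascending; the lower cluster is the producers), with per-bin mean
profiles alongside. Ties in restart quality resolve toward the lower
cluster index through the fixed seed.

`bimodality_check` audits the two-cluster assumption: Calinski–Harabasz
over k = 2..4 selects a candidate, and the k = 2 silhouette is compared
against its distribution under a unimodal Gaussian null with the
*empirical covariance* of the trajectories (bins are nearly collinear;
an independent-bin null would be trivially beaten). If the observed
silhouette does not exceed the null's 95th percentile, k = 1 is
reported.

## Mixed models and repeatability

The scrounging model is binomial with a logit link: per bird,
`n_scrounges` successes out of `n_scrounges + n_solves` trials, fixed
effects (age, sex, first-contact time, latency to learn, exploration,
total rewarded visits as a control, optionally one social metric — the
metrics are correlated, so one model per metric) and a Gaussian random
intercept for replicate. Covariates are standardized before fitting; the
reported coefficients are on that scale.

Estimation is maximum likelihood with the random effect integrated out
by adaptive Gauss–Hermite quadrature (15 nodes; per-group re-centring at
the mode and re-scaling by the curvature). Wald z and p come from the
numerically differentiated Hessian. When σ̂ collapses below 10⁻³ the
model is refitted as a plain GLM with a warning (the models coincide at
σ = 0); complete separation raises an explicit error. The fit agrees
with `lme4::glmer(nAGQ = 15)` to ~10⁻⁵ on shared test data, and that
agreement is frozen as a test oracle.

Repeatability treats every rewarded event as a binary outcome
(scrounge = 1) with date and replicate fixed effects and a bird random
intercept. On the default latent scale R = V_ind / (V_ind + π²/3), the
logistic link-scale residual variance being fixed; `scale="original"`
instead decomposes variance on the observation scale by quadrature over
the fitted intercept distribution. Both are reported because the
variance-ratio definition is scale-ambiguous for binary data. The
confidence interval is a percentile parametric bootstrap (default 500
refits; identical likelihood is preserved by aggregating event rows to
binomial counts per bird × covariate pattern).

The replicate-level analysis regresses the proportion of
scrounger-labelled birds on subpopulation size (all birds detected at
puzzle-boxes in the replicate) by OLS with year as a categorical
control.

## The synthetic-data generator

No field dataset is deposited, so the generator is a first-class,
tested component that emulates the study design: five subpopulations of
40–102 birds; three puzzle-boxes per subpopulation running 06:00–18:00
on 20 weekdays at ~170 rewarded visits per box per day; eight feeders on
10 weekend days; 1/16-s timestamp quantization. "Dawn/dusk" is
abstracted to the fixed 06:00/18:00 bounds. Per-bird latent traits:

* **θ_i** — probability a rewarded visit is attempted as a scrounge,
  drawn from a two-component Beta mixture (means 0.27 / 0.86,
  concentration 45, baseline weight 0.30 on the scrounger mode) rather
  than point masses, so clustering faces realistic within-cluster
  variance. A bird with θ_i ≥ 0.5 is a scrounging specialist in ground
  truth.
* **s_i** — sociability (lognormal, σ = 0.6), the propensity to join
  gathering events.
* **λ_i** — learning latency (lognormal, median 400 s, σ = 0.5): the
  closed-door exposure a bird needs before it can solve. Calibrated so
  solving spreads within a day or two of first contact, matching the
  rapid diffusion the study system shows; two pre-trained demonstrators
  per subpopulation seed the behaviour.
* **arrival day** — geometric (p = 0.35) over weekdays.

Tactic adoption is a threshold decision on the adoption logit:
logit p = logit(w·κ(n)) + γ_s·z(s) + γ_λ·z(log λ) + γ_a·z(arrival), with
κ(n) = clip((n/70)^1.5, 0.2, 2.0). The κ term makes scrounging
opportunity — co-presence at the box — rise with subpopulation size, so
the group-size → scrounger-frequency pattern *emerges* from individual
decisions (adoption ~0.13 at n = 40 up to ~0.53 at n = 102, the span the
replicate-level relationship in this study system shows) rather than
being hard-coded per bird; because the mixture component means do not
depend on κ, the 0.27/0.86 calibration is invariant to subpopulation
size. γ_λ = 0.8 and γ_a = 0.5 encode that slower learners and later
arrivals scrounge more; γ_s defaults to 0 (independence) so calibration
studies of the permutation test run under a true null, and is raised for
power studies.

Puzzle streams: rewarded visits per box-day are Poisson(170), allocated
to present birds by activity weights (producers 2.2× — producers make
many more rewarded visits; this also places the visit-weighted scrounge
fraction near one third). Intended scrounges attach to solve chains with
open slots (at most 3 followers, distinct birds, follower gaps drawn on
the tick grid strictly inside the window); intended solves by birds that
have not yet learned become closed-door contacts, which accumulate
learning exposure along with Poisson baseline contacts (12/day,
~26 s each). Chains and contacts are laid on the day's timeline with at
least window + 0.5 s separation, so the event engine reconstructs the
generator's intent exactly — a property the tests assert. Learning is
resolved at day granularity: a bird crossing λ_i during day d solves
from day d + 1.

Feeder streams: gathering events arrive per feeder-day with lognormal
gaps (mean 40 min, σ = 0.5) and Gaussian within-event detection times
(sd 2 min); members are drawn with probability ∝ s_i, scaled so the mean
event size hits the 7.9-bird target. Feeders differ in traffic
(lognormal busyness, σ = 0.6) and sociable birds preferentially use busy
feeders, giving birds genuinely different typical group sizes (roughly
5–16) and a positive strength × group-size correlation. Each member
triggers the antenna ~2.5 times per bout, keeping the per-event
detection count compatible with the ⌈n/5⌉ component cap.

A single seed feeds one RNG substream per subpopulation, so output is
byte-identical across reruns and stable under adding subpopulations.
`simulate_gbi` is an event-level shortcut (same membership model,
including within-stratum event-size heterogeneity and optional
sociability–size preference, no clock rendering) for calibration studies
of the network stages.

**What the generator does not emulate:** spatial movement and
energetics; within-day visit-rate rhythms (rates are homogeneous inside
the active window — the study system's rhythms are undocumented);
displacement scrounging at the open door; mortality between years
(multi-year data are independent draws); a bird can in principle appear
at two boxes simultaneously (box streams are generated independently;
no analysis uses cross-box simultaneity). Passing recovery tests
therefore shows the estimators work under temporally clustered,
margin-realistic data with known truth — not that the field data meet
these assumptions.

## Problem sizes in the test suite

Recovery and calibration studies run at desk scale, chosen as the
smallest sizes at which the estimators' sampling error is well inside
the asserted tolerances: tactic recovery uses 50 generator seeds of one
70-bird subpopulation over 20 days; repeatability recovery 200 birds ×
100 events; mixed-model recovery 300 birds × 4 replicates over 50
seeds (type-I over 200); permutation calibration 200 datasets at
n_perm = 1000; the end-to-end size→scrounger-share check 50 runs of ten
replicates (two years × five subpopulations). The replicate-level share
is computed at the ≥20-visit threshold: the reward budget is fixed per
box-day, so per-capita visits shrink with subpopulation size, and a
50-visit cut selectively thins low-activity birds in large
subpopulations — biasing exactly the contrast under study. (Threshold
robustness at ≥10/≥20 is an explicitly checked property of this study
design; the 50-visit default applies everywhere else.)

## Known limitations

* The GMM stand-in for gathering detection is 1-D (time only), per
  feeder-day; the richer published detection methods (velocity/overlap
  criteria) are out of scope by design.
* Betweenness is binarized; weighted variants are not implemented.
* The bootstrap CI for repeatability is percentile-based and can be
  slightly narrow at small bird counts.
* Wald z-statistics are reported without degrees-of-freedom corrections;
  with few grouping levels the random-intercept variance itself is
  poorly determined (coefficient inference on within-group covariates is
  unaffected in the type-I checks).
* The permutation chain's mixing heuristic (ones/10 per step) was chosen
  by calibration on small matrices; very large, very sparse GBIs may
  need more attempts per step.
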