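# Methods

## The model

The package models transcriptional roadblocking in *E. coli*: a
sequence-specific DNA-binding protein (the lac repressor LacI in the
reference system) bound between a promoter and a reporter pauses
elongating RNA polymerase, and the fate of the paused polymerase sets the
fraction of transcription that survives downstream of the site
(readthrough fraction, Rf; 1 = no roadblocking, 0 = complete block).

The lattice is the promoter–spacer–operator DNA segment in 1 bp units,
transcription start at +1.  An RNAP occupies a 30 bp footprint, advances
1 bp per time step (dt = 1/40 s, i.e. 40 bp/s), and is introduced by
promoter firing at rate `k_F` whenever no footprint overlaps the +5
position.  The roadblocker binds its 20 bp operator at rate `k_B`
(repressor concentration × on-rate constant 2.51 × 10⁶ M⁻¹s⁻¹) whenever
the operator is free of RNAP, and unbinds at `k_U` (set by the operator's
relative dissociation constant: 1 : 5.2 : 22.9 for the ideal, medium and
weak lac operators).  An RNAP meeting the bound roadblocker (or a paused
RNAP ahead) pauses; a paused RNAP is terminated (removed) at `k_T`, or
dislodges the roadblocker at `k_SD` when alone and `k_MD` when at least
one trailing RNAP is queued in direct contact.  No backtracking,
sequence-dependent pausing, ribosome coupling or promoter bursting is
modeled.

The reference unbinding rate of the ideal operator is calibrated
internally from its stationary vacancy at 250 nM repressor
(k_U/(k_B+k_U) = 0.07%, giving k_U ≈ 4.40 × 10⁻⁴ s⁻¹) rather than from an
external Kd table; this keeps every derived occupancy and escape bound
consistent with one anchor.

## Stochastic simulation

A hybrid of fixed-step and event-jump updating.  Each dt applies, in
fixed order: promoter firing → operator binding/unbinding → dislodgement
attempt by the roadblock-paused leader → termination of paused RNAPs →
1 bp advancement (leading RNAP first).  All stochastic events are
Bernoulli with p = 1 − exp(−rate·dt); at the largest rate in the system
(0.63 s⁻¹) this is p ≤ 0.016 per step, so the discretization bias is
O(rate·dt) and far below Monte Carlo noise at the simulated sizes.  The
fixed phase order is an O(dt) choice made for reproducibility.

Two uneventful states are advanced by exact exponential waits instead of
stepping: the empty lattice (a two-state operator chain plus Poisson
firing) and a lone RNAP paused at the bound roadblock (competing firing,
escape, single dislodgement, termination).  Both jumps are exact in the
continuous-time limit and statistically indistinguishable from stepping
at O(dt); they make the weak-promoter regime (mean pause ≈ 15 s, firing
intervals up to hours) computationally free.  The low-flux
oracle-equivalence test (below) exercises both jump paths.

Runs are deterministic given (config, seed).  Simulations start with the
operator bound and the lattice empty — within 0.2% of the stationary
state for every condition on the design grid, which is why the default
burn-in is zero; a burn-in window is available for parameter regimes far
from that start.

A passing RNAP is recorded when its front crosses the operator's
downstream edge, but stays on the lattice until its rear clears the
operator, so a follower's binding window is the full
(operator + footprint)/velocity = 1.25 s gap.

Rf is measured as in the reporter assay: the pass rate with the
roadblocker present divided by the pass rate with k_B = 0, over paired
seeds and durations (variance reduction; the single-run pass-per-fire
probability is also exposed).

### Mechanism attribution

Each pass carries exactly one label.  A pass by the RNAP whose
dislodgement event removed the roadblocker is `SD` or `MD`; a
roadblock-paused RNAP resumed by spontaneous unbinding is `escape`.
Unimpeded passes are classified by the operator's recent history:
`occlusion` if footprints have covered the operator continuously since
the previous pass (this is how a queue released by one dislodgement gets
its "free pass"); otherwise `facilitated_absence` if the standing vacancy
originated from a dislodgement, and `absence` if it originated from
spontaneous unbinding or the roadblocker never bound.  Absence and escape
are reported separately but are typically merged (A+E) in summaries.

### Clogging

The promoter is "clogged" while the footprint covering the +5 reload
position belongs to a paused RNAP (stalled at the roadblock or queued
behind a stall).  Transient occlusion by a freshly fired, freely
elongating RNAP is excluded.  The 102 bp spacer holds four stalled
RNAPs (fronts 102/72/42/12) before blocking the promoter; a 30 bp spacer
holds one.

### Model variants

* `termination_protection`: only the promoter-proximal paused RNAP is
  subject to k_T (a trailing RNAP shields the leader from the
  termination machinery).
* mfd deletion: k_T = 0.0045 s⁻¹ (14-fold below the wild-type 0.063)
  and both dislodgement rates divided by 3 (the fitted decreases were
  2–4-fold).
* The "queued" criterion for k_MD defaults to direct contact (front
  spacing exactly 30 bp) with the paused leader; `queue_rule =
  "any_paused"` switches to any trailing paused RNAP.

## Analytic low-flux solution

When k_F ≪ k_T + k_U + k_SD each RNAP meets the roadblock alone and

    Rf = k_U/(k_B+k_U) + [k_B/(k_B+k_U)] · (k_SD+k_U)/(k_SD+k_U+k_T),

the avoidance term plus the probability a pause resolves by dislodgement
or escape before termination.  This two-term competing-rates form is the
minimal model consistent with the avoidance/escape/dislodgement
decomposition; it is validated against four printed special cases (the
0.67% escape bound, the 98% and 68% fast-unbinding extrapolations, the
98.9% occupancy consistency) and, independently, against the stochastic
simulator at k_F ≤ 10⁻³ s⁻¹ (agreement within 3 Monte Carlo standard
errors — the central correctness test of the simulator).

The occupancy-preserving tuning surface holds k_B/(k_B+k_U) fixed while
sweeping k_U, coupling k_SD to k_U through a power law fitted through the
ideal- and weak-operator anchors (exponent ln 4.2 / ln 22.9 ≈ 0.458,
i.e. ~2.9-fold k_SD per 10-fold k_U).  Rf rises monotonically along the
surface: binding kinetics can be tuned to keep a site occupied while
shedding its roadblocking cost.

## Parameter fitting

(k_T, k_SD, k_MD) are fitted to an Rf table by simulated annealing on a
least-squares objective; k_B and k_U are never fitted (they are fixed by
concentration and affinity).  k_T is shared across operators; k_SD and
k_MD are per operator.  Design choices where the procedure was open:

* Objective: sum of squared Rf residuals; all Rf share the 0–1 scale.
  CI-weighted least squares (weights 1/CI²) is available via a flag.
* Common random numbers: each row's simulation seed is a fixed function
  of (fit seed, row index), so the objective is a deterministic function
  of the parameters and Monte Carlo noise largely cancels between
  neighboring proposals.
* Proposals: multiplicative log-normal, one parameter per move,
  round-robin, plus a correlated scaling of all free rates (the
  landscape is soft along that direction — at low flux the data see rate
  ratios before absolute rates); the step size can be annealed down
  across the schedule (default σ = 0.2, constant).
* Schedule: geometric cooling from T₀ = the initial objective.  Short
  schedules are made robust by an optional coarse log-grid
  initialization (`init_grid` points per axis, ranked with a cheaper
  objective), and with a Monte Carlo objective candidate bests can be
  confirmed by an independent re-evaluation (``confirm_best``) to avoid
  winner's-curse selection of lucky draws.
* Default bounds on the fitted rates are (10⁻⁴, 1) s⁻¹ — timescales of
  1 s to ~3 h, the window the promoter ladder can resolve.
* Each objective evaluation simulates a fixed wall-clock window per row
  (fires/k_F seconds) so the paired roadblocker-free run shares the
  duration.

``fit_rates`` is the recommended end-to-end pipeline.  The landscape has
a soft common-rescaling ridge and can hold a secondary local basin at
roughly 20-fold-scaled rates (pauses resolving within ~1 s mimic much of
the curve at the grid's resolution), so single-start optimization is
unreliable.  The pipeline therefore: (1) scans a coarse log grid over
the bounds; (2) takes the top few mutually distant candidates, pulls
each down the ridge with a joint-rescaling line search, and locally
optimizes it by cyclic coordinate line searches — with common random
numbers the objective is deterministic, so pattern search converges far
faster than a cooled random walk; (3) re-ranks the refined candidates at
high fidelity, passes the winner through a short cold annealing stage,
and finishes with a final coordinate refinement.  Convergence is
additionally diagnosed by the landscape operation (objective over a 2-D
parameter slice, others clamped).

## Synthetic data

The generator reproduces the design of the reporter-assay grid: 15
log-spaced promoters spanning the 611-fold firing-rate range
(3.3 × 10⁻⁴ … 0.2 s⁻¹), operators Oid/O1/O2, repressor concentrations
250/120/70/35/15 nM, spacers 102/60/30 bp, wild-type and mfd-deletion
genotypes, n = 9 replicates.  The strongest promoter is excluded from
the short-spacer grids (its sequence would overlap the shortened
window).  Replicate noise is Gaussian on Rf with sd = 0.1·Rf + 0.005,
truncated at zero, and rows carry the replicate mean and Student-t 95%
CI.  Noise is applied to Rf directly — raw reporter units and
background subtraction are never modeled.

The underlying Rf per cell is itself a finite simulation (default 2000
expected firings per cell; recovery experiments use 4000), so generated
tables carry a small extra Monte Carlo component on top of the replicate
noise.  What passing recovery tests show is therefore that the inference
machinery is consistent — not that real reporter data are this
well-behaved: real measurements add growth-condition drift, background
subtraction error and promoter-calibration uncertainty that the noise
model does not emulate.

The fixture rate map uses the published best-fit values; the
intermediate operator's dislodgement rates were never published and are
geometric means of the flanking anchors, labeled synthetic.

## Problem sizes and numerical choices

Default problem sizes used by the test suite and benchmark script:
10⁴–3 × 10⁴ firings per simulated Rf point (Monte Carlo SE on Rf about
0.002–0.005); recovery experiments use a 15-row table generated at
2 × 10⁴ firings per cell and the fitting pipeline's defaults (8³-point
coarse grid ranked at 600 firings per row, three scale-distinct starts,
coordinate refinement at 4 × 10³ and 9 × 10³ firings per row).  These
sizes were chosen so that every checked quantity is resolved
several-fold finer than its acceptance band.

Degenerate inputs: an all-zero (k_SD, k_U, k_T) pause is absorbing and
detected; k_B = 0 gives Rf = 1 exactly; saturated promoters (headway 0)
are valid and simply floor the mean-headway arithmetic at zero.  Ties in
the advancement order are resolved leading-RNAP-first, which keeps
lockstep queues intact.

## Known limitations

* Rate recovery from a single synthetic table is reliable but not
  guaranteed: the secondary high-rate basin occasionally wins when none
  of the multi-start candidates refines deep enough into the true basin
  within the time budget.  A clearly elevated final objective (several-
  fold above the replicate-noise floor) flags such runs; rerunning with
  another seed or inspecting the landscape operation resolves them.

* The analytic form omits the O(k_F) corrections (second-RNAP arrivals
  during a pause), visible as a ~+0.002 excess of simulated Rf over the
  formula already at k_F = 10⁻³ s⁻¹.
* One fitted arithmetic inconsistency in the source material is
  reproduced as arithmetic, not as the printed number: the weakest
  promoter (k_F = 3.3 × 10⁻⁴ s⁻¹) fires 0.066/0.00033 = 200-fold slower
  than paused RNAP terminates, not 220-fold.
* The 30/60 bp spacer anomaly is handled, as in the source analysis,
  purely by refitting k_SD per spacer; no σ⁷⁰-retention mechanics are
  modeled.
* Termination removes the RNAP instantly; any finite falloff time is
  absorbed into k_T.
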