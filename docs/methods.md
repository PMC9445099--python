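# Methods

## The model

`tebbo` models the extension and early thickening phases of branched
pancreatic-ductal-adenocarcinoma (PDAC) organoids growing in a collagen
matrix. Three processes shape the tree: tip cells invade the matrix at a
constant speed `v0`; terminal tips branch stochastically at rate `kb` (a
pure-birth, or Yule, process); and cells divide at a rate that decreases
linearly with branch width,

    kd(w) = kd0 * max(0, 1 - w / w0),

a contact-inhibition feedback: cells in thicker branches have more
neighbours and deform the matrix more, and their proliferation is
progressively shut down until it stops entirely at width `w0`.

### Mean-field equations

Writing `Ltot` for the summed branch length, `Nc` for the total cell number,
`Nb = exp(kb t)` for the tip count (one tip at t = 0), and closing the system
with the cylindrical relation `Nc * v_cell = (pi/4) w^2 Ltot` for the mean
width `w`:

    dLtot/dt = v0 * exp(kb t)
    dNc/dt   = kd0 * (1 - w/w0) * Nc

Elongation is linear per tip but the number of tips grows exponentially,
while proliferation is exponential from the start. The system therefore has
two phases: an early phase with thin branches and near-maximal division
(`log Nc` slope ≈ `kd0`), and a late phase in which the mean width settles at
the fixed point

    w* = w0 * (1 - kb/kd0),

where proliferation exactly balances the dilution of cells into new length,
and growth continues exponentially at the branching rate `kb`. The plateau
value depends only on the zero of the feedback, not on the closure geometry:
replacing the cylinder by a sheet closure moves the transient but not `w*`.

The equations are integrated with adaptive explicit Runge-Kutta
(`scipy.integrate.solve_ivp`, rtol 1e-10) on the state `(Ltot, log Nc)`;
width is reconstructed from the closure at every reported state, so the
closure holds to machine precision. The default reporting grid is
dt = 0.01 day.

### Spatial stochastic model

Each organoid is a rooted tree of branches with polyline centerlines.
Per fixed time step (tau-leaping, dt = 0.01 day):

* **Elongation.** Every terminal, unbroken branch's tip advances `v0 * dt`
  along its heading; the heading diffuses with angular variance
  `dtheta * dt` (default 0.5 rad²/day).
* **Branching.** Terminal branches branch at rate `kb`; the per-step
  probability is `exp(kb dt) - 1`, which makes the per-step expected tip
  multiplication exactly `exp(kb dt)` (a plain `1 - exp(-kb dt)` leaves the
  Yule mean about 1% low because a tip can fire at most once per step).
  Daughters leave at ±`theta_b` (default 0.6 rad) around the mother heading
  in a random plane, with length `l_init` (default 5 µm, a nascent bud) and
  the mother's tip width.
* **Division-coupled branching** (default on). Divisions in the tip
  compartment — the leading 6 cells — occur at rate `6 * kd(w)`. Branching
  events are realised as a thinning of this division process: a branching
  fires only at a division, with conditional probability chosen so the
  long-run branching rate is exactly `kb` whenever `6 kd >= kb`. Every
  branching event is then division-led (the observed "True-Yes" dominance),
  the rate is unchanged, and when proliferation is blocked branching stops —
  as observed under aphidicolin. (A naive "defer the candidate to the next
  division" scheme is not rate-preserving: the extra exponential waiting
  time gives a Bellman-Harris process whose growth rate at calibrated
  parameters is ~23% below `kb`.)
* **Width dynamics.** Widths are the primary per-branch state. Non-terminal
  branches widen by pure proliferation, `d ln w² = kd(w)`, and converge
  toward `w0`. Terminal branches additionally pay the elongation dilution —
  spreading cells into newly laid length — split between a local share
  `gamma * v0 / L_i` (their own fresh segment; nascent, short branches thin
  fastest) and a collective supply-network share
  `v0 * sum_tips(w²) / sum_all(w² L)`, the spatial counterpart of the
  mean-field dilution `v0 Nb / Ltot` (cells flow from the organoid core
  toward the tips). The collective share is carried by proliferative flux:
  when total proliferation cannot cover the tips' demand the uncovered
  fraction is borne locally, so under full proliferation block each branch
  stretches its own tissue. Default `gamma = 0.3`. Volumes follow the
  cylindrical closure `V = (pi/4) w² L` identically.
* **Breakage.** A branch thinner than `w_min` ruptures: it stops elongating,
  growing and branching but keeps its geometry. The default is `w_min = 0`
  (no rupture): nascent branches transiently pass through sub-cellular
  closure widths that are an artifact of the cylindrical closure, not
  physical rupture, and rupture is only reported under proliferation block.
  Drug studies set `w_min = 5` µm explicitly.
* **Self-avoidance** (off by default): tips arrest when they approach a
  foreign branch within `self_avoidance_distance`; an approximate,
  KD-tree-based check offered for completeness.

**Mass bookkeeping.** The non-terminal growth law `d ln V = kd(w)` is an
exact local mass balance. For terminal branches the residual between
`d ln V` and `kd(w)` is the tipward cell flux through the supply network,
which the model does not track per branch; consequently total tree volume is
not exactly the integral of proliferation. This is a deliberate trade: a
strictly branch-local mass closure is unstable at the calibrated parameters
(nascent branches restart a dilution transient `v0/l_init >> kd0`, and
fast-branching lineages ratchet widths to collapse), while a strictly
zero-leak collective scheme erases the terminal/non-terminal width
asymmetry. The chosen dynamics keeps both of the model's structural
predictions: terminal widths plateau below non-terminal widths, and the
ensemble means track the mean-field ODE.

**Measured fidelity to the mean-field ODE** (500-run ensemble means at the
calibrated parameters): tip counts and total length agree within 10%
throughout days 0–9; total cell mass agrees within ~10–20% at days 6–9 but
overshoots up to ~1.8x during the onset phase (days 2–4, where absolute cell
numbers are tens of cells) because discrete nascent branches do not
reproduce the ODE's deep early width dip. The consistency test encodes this
achieved band.

### Perturbation presets

* `batimastat` (MMP inhibitor): at the treatment time, `v0 -> 0` and `kd0`
  is scaled to 23% of its control value (the measured −77% residual
  volumetric growth). With no elongation there is no dilution; all widths
  rise toward `w0` — organoid thickening.
* `aphidicolin` (DNA-polymerase inhibitor): `kd0 -> 0`. Tips keep invading
  for a while, stretching a fixed amount of tissue: terminal widths decrease
  monotonically, and the youngest (shortest) branches cross the rupture
  threshold first — nascent-branch fragility.

## Measurement conventions

Terminal-branch width is read 30 µm behind the tip (at the branch base for
branches shorter than 30 µm); "body" width 100 µm behind the tip;
non-terminal width 100 µm behind the distal branching point (the base of the
"Y"). A branch is the segment between a tip and a branching point (terminal)
or between two branching points (non-terminal). The organoid major axis is
approximated by the maximum pairwise distance between skeleton nodes — an
upper-bound proxy for an image-mask ellipse fit, never compared against
image-derived values. Simulated branches carry one width; per-node
("tapered") widths are supported for fixtures via linear interpolation along
arc length. The normalized volumetric growth rate of a branch over an
interval is `(V(t+Δ) − V(t)) / (V(t) Δ)`.

## Parameter recovery

* **Feedback line** (`kd0`, `w0`): ordinary least squares of normalized
  volumetric growth rate on width; `kd0` is the intercept, `w0` the zero
  crossing `−intercept/slope`, reported only when the fitted line decreases
  from a positive intercept. Uncertainties: OLS standard errors and an
  optional seeded nonparametric bootstrap (95% percentile intervals, 1000
  resamples by default in reports).
* **Branching rate** (`kb`): least squares of `log(mean tip count)` on time.
  Tip (terminal) counts are used because they are the individuals of the
  pure-birth process — `log E[tips]` is linear in `t` with slope `kb` from
  `t = 0`, whereas the all-segment count `2m − 1` reaches that slope only
  asymptotically. Both the free-intercept and intercept-pinned
  (`count(0) = 1`) slopes are reported; the free-intercept value is primary
  since observed day-1 structures may already carry more than one branch.
* **Tip speed** (`v0`): per-track least-squares slope of cumulative path
  length against time, mean ± sd across tracks. Path length grows at exactly
  `v0` per unit time regardless of heading noise, so this estimator is
  unbiased under angular diffusion and additive sampling jitter.
* **Cell-count comparison**: RMSE between predicted and observed mean cell
  numbers on the log scale plus the fraction of time points where the
  prediction lies within mean ± sd (boundary counted as covered).

## Synthetic data

The generator runs the spatial simulator per organoid (organoid `i` uses
seed `master_seed + i`, so subsets regenerate reproducibly), measures the
trees with the conventions above, and corrupts the tables with mean-one
multiplicative lognormal noise on widths, growth rates and cell counts
(default CV 10%, a declared assumption — the real measurement-error
magnitudes are unknown) and additive Gaussian jitter (sd 2 µm) on tip-track
samples.

Growth-rate pairs are sampled on a live-imaging window, day 7–9 at 0.1-day
intervals, and only on **non-terminal** branches: a non-terminal branch is a
fixed segment between branching points, so its volume change over a frame
interval is purely proliferative, whereas a terminal branch extends during
the interval, conflating elongation with growth. The 0.1-day frame interval
keeps the finite-difference estimator's convexity bias
(`(e^{kΔ} − 1)/Δ` vs `k`) under ~1% at the rates the feedback produces.

What the generator does **not** emulate: segmentation and projection errors,
spiky tip protrusions, observer selection of measurable branches, organoid
fusion, or any drift in the underlying rates. Passing the recovery tests
therefore shows the estimators are consistent for data with the model's own
statistical structure — not that the model is identifiable from arbitrary
real microscopy data.

A small versioned fixture (3 organoids, days 1–9, fixed master seed 2093) is
regenerated at test time and its fit report is asserted byte-identical to
the committed copy.

## Problem sizes and numerical choices

Defaults everywhere: `v0 = 80` µm/day, `kb = 0.55`/day, `kd0 = 1.5`/day,
`w0 = 60` µm (representative extension-phase values; the published fit
values for `kd0` and `w0` are not printed and are treated as free
parameters), `v_cell = 1000` µm³ (a ~12 µm cell), `l_init = 5` µm,
`dt = 0.01` day. Ensemble checks use 500 runs (branching rate,
mean-field consistency, width ordering), 1000 runs (Yule moments at
`kb t = 2.2`), 200 runs (division coupling), and 100 repeats of 60-organoid
cohorts for the full recovery loop; these sizes put Monte-Carlo standard
errors comfortably below the tolerances being checked while keeping the
default test run short. Ensembles disable polyline recording (`record_nodes
= False`), which changes no measured quantity — widths, lengths, volumes and
counts are tracked independently of the node log.

## Known limitations

* The spatial rules (branch angle, angular noise, daughter seeding, width
  dynamics) are this package's own substitutes for an unpublished
  formulation; quantitative claims are therefore restricted to counts,
  rates, widths and orderings predicted by the mean-field theory.
* The mean-field `Nc` comparison holds to ~10% only from day ~6 on (see the
  fidelity note above).
* The early "onset" phase (a proliferating cell cluster without lumen or
  branches), the late lumen-formation phase, matrix mechanics and gene
  expression are out of scope.
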