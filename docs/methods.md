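# Methods

## Model structure and assumptions

The model tracks the two dominant islet cell types, β (insulin) and α
(glucagon), as lumped populations with no cell-to-cell heterogeneity
and no electrophysiological detail: the stimulus-secretion cascade
(glucose uptake, ATP/K_ATP, Ca²⁺ entry) is collapsed into a single
first-order transduction step per input,

    dX_i/dt = k_i ([i]/[i]_ba − X_i),

so each intracellular signal X relaxes toward the bulk concentration
normalized by its basal level.  Normalization puts glucose (mM),
insulin and glucagon (pg/mL, differing by orders of magnitude) on a
common dimensionless scale.  The four signals are glucose-in-β
(X_gB), glucagon-in-β (X_G), glucose-in-α (X_gA) and insulin-in-α
(X_I); glucose transduction can differ between the cell types (k_gB ≠
k_gA), and hormone signals propagate faster than glucose signals
(k_I > k_gB), consistent with the physical juxtaposition of α- and
β-cells.

Net stimulation signals combine the inputs:

* β-cells: `X_B = X_gB + Hill(X_G; m_GB, h_GB, n_GB) · Hill(X_gB; 1,
  h_gB, n_gB) + X_B0`.  The glucagon boost saturates and is gated by
  glucose (no potentiation without glucose); X_B0 accounts for the
  secretion observed at zero glucose.
* α-cells: `X_A = X_gA − (m_g X_gA + X_A0) · Hill(X_I; 1, h_IA, n_IA)
  + X_A0`.  Insulin acts as a saturating brake that can remove at
  most the fraction m_g (= 0.60 by default) of the glucose drive plus
  the whole background X_A0.  That ceiling is what lets glucagon
  escape suppression at high glucose and is the origin of the
  U-shaped response of intact islets.  For m_g ≤ 1 the signal cannot
  go negative; the implementation clamps at 0 and the parameter
  container warns if a user sets m_g > 1.

Glucose is taken to *stimulate* isolated α-cells (the net signal is
increasing in X_gA); the U-shape of intact islets then emerges purely
from insulin feedback plus the m_g ceiling, not from direct glucose
inhibition.

Secretion kinetics use a three-pool granule model per hormone:
reserve → docked (P1) → readily releasable (P2) → medium, with
forward-only transitions.  The reserve pool is treated as unlimited,
and its outflow into P1 is set to the steady-state secretion rate
R(X); transfer coefficients k1(X), k2(X) are Hill functions of the
net signal.  Consequences: the secreted flux k2·P2 equals R(X) at any
fixed point (flux conservation), the pool subsystem is linear in
hormone mass (scaling the secretion maximum scales pools and fluxes
exactly), and a step in glucose produces the biphasic
first-phase-peak/plateau pattern because the pre-step pool content is
released through transiently mismatched transfer coefficients.
Glucagon kinetics reuse the insulin pool parameters (m_G1 = m_I1
etc.), reflecting the similar exocytotic machinery of the two cell
types.

## Chamber coupling

Cells sit in a well-mixed volume V.  Batch (static incubation):
hormones accumulate, `d[H]/dt = r_H/V`, and glucose is clamped at the
level the experimenter set — islet glucose consumption is not
modeled.  Perifusion: a CSTR balance `d[H]/dt = r_H/V + (Q/V)([H]_in −
[H])`.  There is no hormone degradation term; clearance happens only
via outflow.  Chamber glucose in perifusion defaults to an ideal step
(instantaneous jump to the inlet value at each step edge), matching
protocols that report step increases; `glucose_ideal_step=False`
switches to CSTR washin dynamics.  Whole-chamber secretion scales as
n_islets/15 because the secretion maxima are calibrated per 15
islets.

The integrated state has 11 components (4 signals, 4 pools, 3
chamber concentrations).  The whole-pancreas scenario treats the
organ as one perifusion chamber: V = 100 mL, 10⁶ islets, Q = specific
blood flow × organ mass = 1.3 mL/min/100 g × 90 g = 1.17 mL/min, with
basal glucose and hormones flowing in.  The type 1 diabetic
configuration sets the insulin secretion maximum m_I and basal
insulin to zero; with no insulin normalizer the insulin signal X_I is
defined as identically zero, so the α-cell side runs as if β-cells
were absent.

## Parameters and basal levels

All 32 kinetic, interaction and secretion parameters ship as the
calibrated human-islet defaults in `ModelParameters()`; units are
1/min for rate constants, pg/min per 15 islets for secretion maxima,
and dimensionless otherwise.  Basal references (`BasalState`) are
g_ba = 5 mM (human fasting glucose) and G_ba = 70 pg/mL (≈20 pM,
mid-range basal glucagon).

The basal insulin normalizer I_ba deserves its own paragraph because
it is the one basal level the coupled behavior is genuinely sensitive
to: X_I = [I]/I_ba sets how strongly accumulated insulin engages the
α-cell brake (h_IA = 10).  The default is I_ba = 100 pg/mL (≈17 pM,
a low-normal fasting level).  At this value (i) a 10-islet batch
incubation accumulates enough insulin within an hour to drive X_I
well past h_IA at intermediate glucose, producing the U-shaped
glucagon response of intact islets, while perifusion at 1 mL/min
washes insulin out and flattens the curve; and (ii) the whole-organ
steady state reproduces observed basal secretion (~3×10⁻³ mg/min
insulin, ~5×10⁻⁶ mg/min glucagon) — there the chamber insulin is
thousands of times I_ba, so those readouts are insensitive to the
exact choice.  Much larger normalizers (≥~350 pg/mL) suppress the
batch U-shape entirely, which is how the default was fixed.  All
basal levels are configuration values, not hardcoded.

Cross-species protocols: mouse experiments are mapped to the human
glycemic set point by multiplying inlet glucose by 0.6
(`rescale_protocol_species`), e.g. a 3→12 mM mouse step becomes
1.8→7.2 mM, and insulin exposure is matched by islet count (the
shipped `mouse_equivalent_step` scenario uses 5000 islets).

## Numerics

Integration uses LSODA (stiff-capable, adaptive) with rtol 1e-8 and
per-component atol (1e-10 signals, 1e-8 pools/hormones, 1e-6 glucose
concentration scale); the output grid is 0.1 min.  Integration
restarts at every inlet step edge so the solver never crosses a
discontinuity, and the edge point appears once in the output grid
(pre-step values).  Hill functions are evaluated in log space,
`m·sigmoid(n(log x − log h))`, because exponents near 10 (n_I1 =
9.97) overflow the naive power form at large signals; x = 0 maps to 0
exactly.  Steady states (perifusion only — batch has no finite fixed
point and is refused) are solved by damped fixed-point iteration on
the chamber hormone concentrations (the cell states are explicit
functions of them at a fixed point), verified by requiring the full
right-hand side to have scaled residual < 1e-10, with a long-horizon
integration fallback.  Time integrals of secretion use trapezoidal
quadrature on the output grid with interpolated window endpoints;
halving the grid changes a 1-h integral by < 0.1 %.

Batch simulations start from the cell fixed point consistent with the
initial chamber fill (hormones at the inlet/basal values, the t = 0
glucose); perifusion simulations start from the full coupled steady
state under the t = 0 inlet.

## Estimation

The objective is a normalized, per-trajectory-weighted SSE:
Σ_traj w · Σ_t ((model − data)/data)², so insulin (tens of pg/min)
and glucagon (single pg/min) contribute comparably.  Optimization is
bound-constrained trust-region-reflective nonlinear least squares
(scipy), restarted from the initial guess plus seeded Latin-hypercube
points spread over the bounds (default 8 starts); the lowest-SSE
solution wins.  The `glucagon_feedback_off` flag encodes the standard
perifusion fitting assumption that secreted glucagon is negligible:
it zeroes m_G and m_GB during fitting (so X_B ≈ X_gB + X_B0) and
drops glucagon residuals.  Fitting simulations default to rtol 1e-6
and a 0.5-min output grid — the model is evaluated at the data time
points by interpolation, and these looser settings change the
objective by ≪ the residuals being minimized.  Named bound presets
from the calibration workflow (h_GB ∈ [500, 1000]; h_IA ∈ [1, 100]
first pass, [8, 100] human refit) are passed as ordinary bounds; a
per-condition mask supports excluding conditions (e.g. a
near-baseline step with negligible response) without code logic.
Grouped fits give selected parameters an independent copy per
condition (the workflow used to re-estimate kinetic constants at each
glucose level) while the rest stay shared.

Sensitivity analysis is one-at-a-time: each parameter is multiplied
by factors {0.66, 0.8, 1.0, 1.25, 1.5} — the largest symmetric range
keeping m_g ≤ 1 — and the readout (15 islets, perifusion at 1 mL/min,
1→15 mM glucose step, started from its own steady state) reports
total 1-h insulin and glucagon.  With the default parameters insulin
totals are dominated by {h_I1, h_I, X_B0, m_I, n_I1} and glucagon
totals by {m_G, h_G1, X_A0}; totals *decrease* as the background
signals X_B0/X_A0 increase because a system starting at a
higher-background steady state holds less releasable hormone in its
pools.

## Synthetic data

The generators emulate the two canonical assay designs: perifusion
time courses (glucose held at a 3 mM baseline, stepped at 8 min to
each test level, fluxes sampled every 2 min for an hour, 15 islets)
and batch totals (1-h incubations at each glucose level, 10 islets).
Defaults mirror those designs; noise is multiplicative Gaussian (5 %
default), reflecting immunoassay error that scales with signal, with
an optional additive floor, clipped at zero.  Ground truth is written
to a sidecar JSON, never parsed from the data file.  What synthetic
data does *not* emulate: inter-islet biological variability, assay
drift and carryover, sampling dead volume, or model misspecification
— recovery tests therefore demonstrate that the fitting machinery
works, not that real datasets of this size identify the parameters.
Hill exponents (n_*) in particular are sloppy and are not asserted in
recovery tests.

## Problem sizes used in the shipped tests

Test and acceptance runs use the experiment sizes of the designs they
emulate: 10–500 islets in 1 mL (batch), 15 islets at 1 mL/min
(perifusion), 10⁶ islets / 100 mL / 1.17 mL/min (whole organ), hour
time horizons, and fitting problems with 3–5 conditions, ~15–30
samples each, 3 free parameters, and 20 noisy replicates for the
recovery statistics.

## Known limitations

* δ-cells (somatostatin), GABA, and incretin effects are absent; the
  predicted T1D hyperglucagonemia (~30-fold) exceeds clinical
  observations, plausibly for this reason.
* No insulin resistance or β-cell mass dynamics: the diabetic
  scenario is the pure T1D limit (m_I = 0), not T2D.
* No glucose consumption by islets and no hormone degradation;
  clearance is advective only.
* The pool model is forward-only; backward (de-priming) transitions
  and β-cell heterogeneity are not represented.
* Parameters are a single calibrated set; species differences beyond
  the 0.6 glucose rescaling (e.g. distinct mouse pool kinetics) are
  supported only by supplying alternative parameter files.
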