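# Methods

## Mixing model

All volume arithmetic is linear: volumes are additive (ideal mixing, no
excess-volume correction) and a component's concentration in a blend is its
volume-weighted mean, `c = Σ cᵢvᵢ / Σ vᵢ`. This is the model a dispensing
robot's calculator implements and it conserves component mass exactly; it
ignores activity coefficients, ionic-strength effects and real-solution
volume contraction, which matter at the few-percent level for concentrated
salt/PEG cocktails but are irrelevant to relative placement of wells on a
grid. Units are declared per component (`mg_per_ml`, `M`, `mM`,
`percent_w_v`, unitless `fraction`) and never converted implicitly; the one
sanctioned conversion (M → mM, the canonical molar unit) runs once at config
load. pH is metadata, not a mixed quantity: a blend keeps a pH only when
every part that declares one agrees, so a buffered cocktail diluted with
water retains its pH while two different buffers yield none.

## Plate design

A plate is defined by four corner conditions (protein mg/ml, primary
precipitant concentration). Intermediate wells are **bilinear** in the grid
indices: position (r, c) maps to (u, v) = (r/(rows−1), c/(cols−1)) and the
target is the standard four-corner blend. Bilinearity is the minimal scheme
with four free corners; it makes every row and column affine in the well
index, so straight concentration gradients can be laid parallel to an
expected boundary (diagonal sampling). Rows index protein (row 0 = the
high-protein edge), columns index precipitant; a `transpose` flag swaps the
convention.

Each well is realized from four channels. With drop volume `V_d`:
`v_protein = V_d·P/P_stock`, `v_cocktail = V_d·c/C_stock` (the whole
cocktail co-dilutes, so all its components scale with the precipitant),
`v_seed = V_d·seed_fraction` when seeding runs on its own channel
(default fraction 0.1; premixed seeding rides inside the cocktail channel
and changes no arithmetic), and diluent takes the remainder. Planning is
exact; plate assembly rounds active channels half-up to the robot
resolution (default 0.01 µl) and pushes the residual into the diluent so
every drop sums exactly to `V_d` — rounding perturbs water, never an active
component. Wells whose channels exceed the drop (`P/P_stock + c/C_stock +
seed_fraction > 1`, beyond a 10⁻³ µl slack) or need a shot below the
minimum dispense (default 0.1 µl) are kept and flagged infeasible rather
than dropped, so coverage reports show the unreachable corner of phase
space. Worklists dispense diluent, cocktail, seed, then protein — bulk
first, the reactive channel last.

## Zone classification

Outcomes are categorical: clear, crystals, shower (a dense microcrystal
shower — same zone logic as crystals, kept distinct for density reporting),
precipitate. The pair (unseeded, seeded) maps to a zone by a fixed truth
table: spontaneous crystals → nucleation; precipitate → precipitation;
crystals only with seed → metastable; both clear → undersaturated;
spontaneous crystals that vanish under seeding → inconsistent (flagged, not
guessed); a missing unseeded arm → unknown, since a clear seeded drop only
bounds the well at-or-below solubility. Zone fractions are taken over
classified (non-unknown) wells.

## Frontier estimation

A phase boundary is modelled as a monotone staircase: a protein threshold
as a step function of precipitant, non-increasing for a salting-out
landscape. Given wells labelled "below"/"above" the boundary, the estimator
minimizes misclassified wells over all monotone staircases whose thresholds
are mid-gaps between adjacent observed protein levels (maximal-margin
placement, with sentinels half a data span beyond the extremes). The search
is a dynamic program over (precipitant level, threshold index) with a
suffix-minimum recurrence — exactly optimal, and checked in the tests
against exhaustive enumeration; among equal-cost staircases the higher
threshold is preferred, deterministically. One-sided inputs degenerate to
±∞ with a warning.

The solubility frontier separates undersaturated wells from all
supersaturated ones; the nucleation frontier separates
{undersaturated, metastable} from {nucleation, precipitation}. A landscape
with competing salting-in and salting-out breaks global monotonicity, so
when the metastable wells form more than one 8-connected grid component the
estimator runs per component (over that component's column span, ±1 column)
and fits each segment in whichever monotone sense scores lower,
reporting multiple disjoint segments. Eight-connectivity is deliberate: a
band tracking a sloped boundary steps diagonally and must not fragment.

## Simulator

Ground truth is the log-quadratic solubility `ln S(c) = ln S0 + beta·c −
K·c²` with supersaturation `σ = P/S(c)` and thresholds `1 < σ_nuc ≤
σ_shower ≤ σ_prec` (defaults 2, 4, 6). This is the simplest smooth family
that produces both the classical landscape (beta = 0, S strictly
decreasing) and the dual-metastable one (beta > 0, S peaks at
c* = beta/2K). The seeded arm crystallizes anywhere in 1 ≤ σ < σ_shower;
the unseeded arm stays clear below σ_nuc except for an optional spontaneous
nucleation probability ramping linearly from 0 at σ = 1 to `p_nuc` at
σ_nuc. `p_nuc` defaults to 0, so the generator is deterministic and
classification must recover the analytic zone map with 100% agreement —
the main end-to-end invariant. One uniform draw is consumed per (well, arm)
regardless of band, so changing a threshold never shifts the stream of a
seeded run; simulation order is row-major, unseeded before seeded.

What the simulator does **not** emulate: time (incubation, Ostwald
ripening), crystal size/density as numbers (shower is categorical),
evaporation (absent under oil by design), spatial drop inhomogeneity, and
scoring noise beyond the nucleation ramp. Passing round-trip tests
therefore shows the pipeline is self-consistent and the estimators are
correct on their model class — not that real plates are noise-free.

## Fixtures

Three deterministic config+model pairs exercise the named topologies on an
8×12, 2 µl plate:

- **classic** — beta = 0 on an ammonium-sulfate-style cocktail; one
  contiguous band per zone, ordered with σ.
- **dual_metastable** — beta = 3.071×10⁻³ /mM, K = 1.0236×10⁻⁶ /mM²
  (solubility peaks at 1500 mM at ten times S0 = 4 mg/ml), giving ≥ 2
  disjoint metastable lobes separated by an undersaturated trough.
- **nucleation_limited** — salting-out only with σ_nuc = 2.23 placed
  between the grid's largest (2.252) and second-largest (2.210)
  supersaturations, so exactly one well nucleates spontaneously while
  seeding crystallizes ~72% of the plate.

## Titration and scale-up

Seed dilution series are analytic factors `step⁻ⁱ` (8 decade levels reach
10⁻⁷); an optional pipetting plan expresses them as physical transfers. A
cross-matrix plate fixes the seed channel volume and varies only the
per-row dilution, so in-drop seed concentration is exactly proportional to
the row factor. Batch recipes split a total volume by ratio weights
(`vᵢ = total·wᵢ/Σw`, the largest part absorbing the float residue so the
sum is exact); the final composition follows from the mixing model and is
independent of total volume. Seed retuning replaces one weight and
recomputes — no kinetic model links seed load to crystal size, so the size
outcome is the experimenter's feedback loop, not a prediction. Reported
volumes print to the nearest integer µl at ≥ 100 µl and to 0.1 µl below.

## Problem sizes and numerical choices

Property suites run on grids up to 8×8 against exhaustive staircase
enumeration (200 random instances), 50 randomized simulator models for zone
recovery, and a 12×12 rectangular grid for frontier-recovery error
(asserted ≤ 1 protein grid spacing wherever the true curve crosses the
column). Feasibility slack is 10⁻³ µl on the diluent; volumes are
normalized to 10 decimal places after rounding so CSV round-trips are
bit-exact. All randomness flows from explicit integer seeds; equal seeds
give byte-identical outputs.

## Known limitations

Precipitant–precipitant diagrams (two cocktail axes) are not modelled — the
grid's second axis is always the designated primary precipitant; seed
particle densities are unitless fractions of neat; the inferred boundary
resolution is one grid spacing at best, by construction; and the
co-dilution arithmetic is reported as computed even where bench protocols
quote rounder numbers (e.g. 0.6 × 167 mM HEPES is reported as 100.2 mM).
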