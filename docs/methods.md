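# Methods

## Model structure and assumptions

The package models homofermentative lactic acid production from glucose,
cellobiose and xylose. Metabolism is assumed strictly homolactic: all
consumed sugar carbon ends up in biomass (C5H7NO2) or lactate (C3H6O3),
with no CO2, acetate, formate or ethanol. Hexoses run through the
Embden–Meyerhof–Parnas pathway, xylose through the pentose phosphate /
glycolytic route, so the theoretical lactate yields at zero cell yield are
2 mol/mol (glucose), 4 mol/mol (cellobiose) and 5/3 mol/mol (xylose).

Writing Y for the molar cell yield, carbon conservation gives the lactate
coefficient n_la = (C_sugar − 5Y)/3 and the hydrogen balance gives the
water coefficient (3Y for the monosaccharides, 3Y − 1 for cellobiose, whose
glycosidic bond consumes one water). Molecular weights are fixed at the
integer values 180/342/150 (sugars), 113 (biomass) and 90 (lactate); with
these the elemental mass balance closes exactly, which
`mass_balance_residual` verifies. The lactate mass yield is always derived
from the carbon-balanced lactate coefficient, Y^la = n_la·90/MW — this is
the only choice for which the tabulated QU 25 yield pairs are mutually
consistent (0.038 → 0.950 g/g on glucose and 0.028 → 1.015 g/g on
cellobiose at three decimals; the xylose pair computes to 0.926 vs a
reported 0.925, consistent with rounding of the fitted cell yield, and the
preset carries the computed value). Yields are stored in g/g throughout; no
percent scaling.

Growth follows Monod kinetics with substrate and product inhibition
(μ_max, Ks, Kis, Kip per sugar); a single pooled lactate concentration
enters every sugar's product-inhibition term. Disabled inhibition is an
explicit infinite-coefficient sentinel (serialized as null in configs), so
the rate law stays branch-free: S²/∞ = 0 and the product factor is skipped
only when Kip is infinite. The rate peaks at S* = sqrt(Ks·Kis) and declines
beyond it.

Carbon catabolite repression is represented, when enabled, by one
non-competitive factor K_ccr/(K_ccr + S_glu) multiplying the xylose rate —
chosen for symmetry with the product-inhibition term. K_ccr has no measured
value; it must be supplied explicitly whenever glucose and xylose coexist
in a run claiming CCR. The G100X50 preset uses K_ccr = 1.0 g/L, which keeps
xylose uptake strongly repressed while tens of g/L of glucose remain — the
qualitative batch co-fermentation behavior — and is never asserted
quantitatively. No temperature or pH dependence is modeled (cultures are
assumed at their fixed optimum), and there is no lag phase or
non-growth-associated product formation.

## Reactor balances

Five ODEs (three sugars, biomass X, lactate) cover batch, CFSTR and
cell-recycle operation. The single generalization over the textbook
chemostat is the cell effluent factor σ = `cell_passes_membrane`: solutes
dilute at the full rate D = 1/HRT while cells leave at σ·D, so the
effective inverse cell retention time is σ·D. σ = 1 recovers the plain
CFSTR (CRT = HRT); σ = 0 is ideal membrane retention, under which the CRT
reported alongside trajectories grows with run time. Membrane
cell-concentration events (e.g. a 10× broth volume reduction) multiply X
and leave solutes unchanged, applied instantaneously at phase start; state
is otherwise carried verbatim across phase boundaries.

Integration uses LSODA (stiff-capable, important near sugar exhaustion)
with rtol 1e-8 / atol 1e-10 and a fixed 0.1 h output grid. Reaction terms
are evaluated on max(S, 0) to prevent spurious negative-substrate growth,
and outputs are clipped at zero. Steady-state detection scans for the
earliest trailing window (default 5 h) in which every state variable's
relative span falls below a tolerance; near-zero variables use a 1e-6 g/L
scale floor. Operating-point summaries report phases that never settle
(e.g. a cell-recycle phase still climbing on the 1/K_D time scale) at their
end state, flagged `no_steady_state`.

## Closed-form steady state

For one sugar under plain Monod growth the balances reduce to
S = Ks(1 + CRT·K_D)/(CRT(μ_max − K_D) − 1) and
X = Y^X·(CRT/HRT)·(S_in − S)/(K_D·CRT + 1), with washout at
CRT ≤ 1/(μ_max − K_D). These expressions intentionally omit the inhibition
terms — the ODE model remains the ground truth where inhibition matters —
and double as an independent oracle: with inhibitions disabled the long-run
ODE solution matches them to 1e-6 relative across dilution rates (part of
the test suite). Steady lactate follows from consumed sugar,
S_la = Y^la(S_in − S). At fixed HRT, X(CRT) is strictly increasing with
diminishing gains toward the decay-limited plateau
Y^X·(S_in − S_min)/(K_D·HRT); there is no interior maximum. Mixed-sugar
steady states come from the ODE simulator only. Sweep tables flag
below-washout and no-growth grid points rather than dropping them.

## Parameter estimation

The fitting objective is the sum of squared differences between simulated
and measured time courses, minimized by `scipy.optimize.least_squares`
(trust-region-reflective, i.e. bounded damped Gauss–Newton of the
Levenberg–Marquardt family) with per-parameter box bounds (defaults:
≥ 1e-6; μ_max ≤ 5 h⁻¹; concentration coefficients ≤ 1e4 g/L) and optional
seeded log-uniform multistart. A sum-of-absolute-differences objective is
selectable (`norm="sum_of_absolute"`) and handled by Nelder–Mead, since
gradient-based least squares requires the smooth L2 form. Standard errors
come from the Gauss–Newton covariance 2·cost/(n−p)·(JᵀJ)⁻¹; near-zero
Jacobian columns and all-zero observation sets raise "unidentifiable"
warnings instead of failing.

A single batch trajectory cannot separate the four growth parameters: along
one batch path S and S_la are deterministically linked, so
μ_max/Ks/Kis/Kip trade off along a ridge. Fits therefore accept a list of
observation sets — batches at several initial concentrations fitted
jointly — which is also how the preset kinetics were originally
determined. When fitting early-exponential batch data, K_D should be fixed
at 0 (decay is informed only by continuous phases or post-exhaustion
decline); the fitting surface leaves K_D out of the free set by default.

BF/AF pairs with non-positive prediction or observation are excluded and
counted. R² is computed as 1 − SS_res/SS_tot per variable.

## Synthetic experiments

The generator reproduces the study protocols as named presets: single-sugar
batches at 10/20/50/100/150 g/L (48 h), mixed batches G100X50 (48 h) and
C100X50 (60 h), CFSTR ladders on C100X60 (D = 0.05–0.25 h⁻¹) and C50X30
(0.05–0.35 h⁻¹) run batch-first and holding each dilution rate for three
retention times, and a cell-recycle run (36 h batch on C50X30, 10×
concentration event, then continuous C50X30 at D = 0.2 h⁻¹ with full
retention, 117 h total). Feed concentrations are nominal. Defaults chosen
once and documented here: inoculum X0 = 0.1 g/L (a 10% v/v transfer of a
late-exponential preculture); decay K_D = 0.02 h⁻¹ (no measured value
exists; this sits in the range typical for lactic acid bacteria and is
small against every μ_max); measurement noise CV 3% with triplicate
sampling every 3 h, matching the scatter of reported triplicate means.

Noise is multiplicative lognormal, value·exp(σz) with
σ = sqrt(ln(1 + cv²)), which has exactly the requested CV and zero log-mean
bias; values are floored at zero. Generation is deterministic per seed and
each observation set ships with a ground-truth manifest (true parameters,
schedule, seed, noise settings).

What the generator does not emulate: by-products, pH/base-addition volume
effects, membrane fouling, incomplete cell suspension, lag phases, and any
variation of yields with growth phase. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Simulations in the tests use the preset schedules directly (≤ 200 h on a
0.1 h grid); Monte-Carlo recovery uses 20 seeds × 5 concentration levels ×
5 replicates with slightly relaxed solver tolerances (rtol 1e-7) for the
inner fitting loops, which leaves parameter estimates unchanged at the
precision asserted. Steady-state convergence runs integrate in chunks of
20/D h until the relative state change per chunk falls below 1e-9–1e-11.

## Known limitations

- The closed-form steady state is single-substrate and inhibition-free by
  construction; use the ODE model for mixed feeds or strong inhibition.
- K_ccr and K_D are not identifiable from the shipped presets' defaults
  alone; they are inputs, not estimates.
- The CRT reported under partial retention (0 < σ < 1) is the instantaneous
  1/(σD), not an age-distribution average.
- Confidence intervals are asymptotic Gauss–Newton approximations and can
  be optimistic near bounds or along stiff parameter ridges.
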