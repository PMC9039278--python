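# Methods

## Scope and model structure

`coroffr` computes steady-state coronary fractional flow reserve on a
centerline representation of the coronary tree. The pipeline has three
layers:

1. **Boundary conditions** (`coroffr.boundary`) map four routine clinical
   measurements (SBP, DBP, HR, CO) to an inlet pressure and per-outlet
   lumped microcirculatory resistances.
2. **Hemodynamics** (`coroffr.hemodynamics`) solves steady flow in the
   vascular domain and couples it to the 0D outlet model by a partitioned
   iteration.
3. **FFR and diagnostics** (`coroffr.ffr`, `coroffr.diagnostics`) extract
   pressure ratios and compute the agreement/classification statistics used
   to benchmark computed FFR against invasive measurements.

The vascular domain is deliberately reduced-order: each segment is a
tapered axisymmetric tube characterised by its length and end radii, and a
spatially resolved CFD solver could be substituted behind the same contract
(inlet pressure and outlet pressures in, interface flows out) without
touching the coupling loop. The steady formulation rests on the observation
that the time-mean of the pulsatile pressure field is what FFR is built
from, so a steady solve with mean boundary conditions reproduces it at a
small fraction of the cost.

## Boundary conditions

* **Mean aortic pressure.** `Pa = DBP + (1/3 + HR·0.0012)(SBP − DBP)`
  (mmHg). This is the standard cuff-based mean-arterial-pressure estimate
  with a heart-rate correction: at low HR it reduces to the classic
  `DBP + PP/3`, and it is monotone in all three inputs over the
  physiological range. With SBP 128, DBP 85, HR 72 it gives 103.05 mmHg.
* **Coronary flow budget.** Resting coronary flow is 4% of cardiac output
  (`coronary_co_fraction`, configurable). The remaining 96% leaves through
  the systemic outlet, whose resistance is `Rdoa = Pa / (0.96·CO)`; mass
  balance at the aortic node is exact by construction.
* **Murray split.** The coronary budget is partitioned among outlets with
  weights proportional to the outlet radius to the power 3
  (`murray_exponent`, configurable), the classical optimal-branching
  exponent.
* **Outlet resistances.** `R_resting = (Pa − Pv)/Q_outlet` with venous
  reference pressure Pv = 0 mmHg by default (`venous_pressure_mmHg`).
  Resistances are always derived from the *healthy* tree's flow budget —
  stenosis descriptors never enter the boundary conditions, only the domain
  solve. Maximal hyperemia multiplies every microcirculatory resistance by
  0.24 (`hyperemia_factor`), the accepted vasodilatory response to
  adenosine.
* **Inertance.** Each outlet carries an inertance L = 0.05 (empirical
  units) for structural fidelity to the pulsatile circuit this model
  descends from. At steady state dQ/dt = 0, so it cannot affect the
  solution; the 0D solver asserts this rather than silently assuming it.

## Segment constitutive law

Pressure drop along a segment at flow q (SI units internally):

    dP(q) = A q + B q |q|

* `A` is the exact Poiseuille resistance of the linearly tapered tube,
  `8 µ L (rp² + rp·rd + rd²) / (3 π rp³ rd³)`, plus, per stenosis, the
  Poiseuille resistance of the throat (radius `r₀(1 − s)` over the lesion
  length, where `s` is fractional diameter reduction).
* `B` sums, per stenosis, the empirical turbulent expansion loss
  `Kt (ρ/2) (A₀/As − 1)² / A₀²` with `Kt = 1.52` by default. This
  viscous-plus-expansion form is the standard reduced-order substitute for
  resolving a stenosis in 3D; it is the principal modelling substitution in
  the package and `Kt` is exposed for calibration.
* Blood is Newtonian with ρ = 1050 kg/m³ and µ = 0.0035 Pa·s; vessel walls
  are rigid and impermeable.

The law is odd in q and strictly monotone, so it inverts in closed form
(`q = 2·dP / (A + sqrt(A² + 4B·|dP|))`), which keeps the network Newton
iteration cheap and robust. Severities ≥ 0.95 are rejected: a
near-occlusion is outside the validity of this loss model.

## Domain solve and coupling

**Domain solve.** With the inlet and all interface nodes held at prescribed
pressures, the unknowns are the interior nodal pressures. Mass balance
residuals are driven below 10⁻¹² of the largest segment flow by Newton with
line-search damping, initialized from the linearized (B = 0) system, which
is exact for unobstructed trees.

**Partitioned coupling.** The domain solve (outlet pressures → interface
flows) alternates with the 0D update (`P = Pv + R·Q` per interface). The
exchanged pressures are updated with the configured relaxation factor
(default 0.5) plus an interface quasi-Newton correction built from the
history of exchanged states (Anderson acceleration with 8 retained secant
pairs, the approach used for stiff partitioned fluid–structure coupling).
Plain fixed-factor relaxation is structurally unstable here — the
microcirculatory resistances exceed the epicardial ones by roughly two
orders of magnitude, so the fixed-point gain per interface is far below −1
— and a per-interface secant rule alone oscillates when several outlets
share a stenosed trunk; the quasi-Newton history handles both.

**Convergence test.** The loop stops when the maximum over interfaces of
(a) the relative change of exchanged pressures, (b) the relative change of
exchanged flows (with a 10⁻⁶ mL/s floor guarding the division), and (c) the
relative pressure mismatch between what the 0D model returns and what the
domain currently uses, all fall below ε = 10⁻⁴. Criterion (c) makes the
norm a true fixed-point residual rather than a stalled-iteration detector;
with it, the partitioned answer agrees with the monolithic oracle to ~10⁻⁵
relative on randomized trees (tested to 10⁻³). Non-convergence raises an
error carrying the full coupling trace.

**Monolithic oracle.** For verification, the outlet resistances are folded
into the network as linear resistor edges to virtual ground nodes at venous
pressure and the whole system is solved in one Newton pass. The partitioned
and monolithic routes are independent paths to the same fixed point and are
compared in the test suite; the oracle is never used as the implementation.

## FFR extraction

`FFR(x) = P(x)/Pa` on the converged hyperemic field, exactly 1 at the
inlet. The lesion value is sampled at the distal node of the host segment —
the deterministic, conservative analogue of a pressure-wire reading just
past the lesion (the wire-to-lesion distance is not standardized in
practice; the distal-node convention avoids an arbitrary offset parameter).
Classification is inclusive: FFR ≤ 0.80 is ischemic, at the boundary too.

## Diagnostics

Positive class = ischemic = FFR ≤ threshold (0.80 default), everywhere.
AUC is the trapezoidal area under the empirical ROC of −FFR_computed
scores, with a DeLong confidence interval; the optimal cutoff maximizes
sensitivity + specificity with ties broken toward the value nearest the
clinical threshold. Pearson CIs use the Fisher z transform (degenerate, and
reported as (−1, 1), at n = 3). The Youden index is reported both at full
precision and truncated (not rounded) to two decimals, since truncation is
how a J of 0.6182 becomes the conventionally quoted 0.61. No
multiple-testing correction is applied: the module reports single planned
comparisons.

## Synthetic data

The generator emulates a CTA-derived coronary tree: an aortic stub
(radius 12.5 mm, length 40 mm — short and wide, so the ostium is
effectively at the prescribed inlet pressure) feeding LAD, LCX and RCA
trunks with proximal radii 2.6/2.3/2.4 mm (±3% jitter), 12–18 mm trunk
segments with 3–5% in-segment taper, and side branches taking 28–40% of the
parent's r³ at each bifurcation, so Murray's law holds to machine precision
by construction. The default (`n_generations = 3`) yields 7 coronary
outlets. Proximal calibers sit at the generous end of normal so that an
unobstructed tree shows < 1% epicardial pressure loss even at hyperemic
flow — the lossless limit a healthy vessel should exhibit. Lesions
(default length 10 mm) are placed on the first trunk segment of the named
branch with severities in the clinically intermediate 40–80% range.

Patient parameters are drawn from stable-angina cohort statistics
(SBP 128±10, DBP 85±9 mmHg, HR 72±12.76 bpm, CO 5.26±2.6 L/min truncated
below at 2, myocardial mass 126±34.08 g as metadata), with rejection
sampling enforcing SBP > DBP > 0.

What the generator does **not** emulate: real lumen irregularity and
eccentric/serial lesion morphology, inter-patient topology variation,
collateral flow, and the segmentation noise of CTA reconstruction. Passing
tests on synthetic trees therefore validate the *solver and statistics
machinery*, not clinical accuracy — establishing the latter requires paired
invasive measurements, which is exactly what the diagnostics module is for.

## Numerical conventions and limitations

* All internal computation is SI; mmHg/mm/mL/s appear only at module
  boundaries (`coroffr.units`).
* Trees are strictly rooted (in-degree 1): anastomoses and collaterals are
  rejected by validation.
* Coronary radii below 0.5 mm warn rather than error, mirroring the ≥ 1 mm
  diameter retention rule of CTA reconstruction while allowing stress
  tests.
* The coupled problem sizes here (≤ ~20 nodes) use dense linear algebra
  throughout; the verification suite runs in seconds on one CPU at these
  sizes by design.
* Resting-state solves use the same machinery with the resting resistances;
  hyperemic lesion FFR is never above the resting value because hyperemia
  raises trans-lesion flow and hence loss.
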