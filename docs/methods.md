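# Methods

`valveverify` re-implements, at desk scale, the verification loop used to
compare a fluid–structure-interaction (FSI) model of a stenotic aortic valve
against bench (mock circulatory loop) experiments: synthetic measurement
data with known ground truth, haemodynamic signal statistics, valve-area
extraction from video frames and from 3D leaflet geometry, a 2D partitioned
FSI solver, stiffness calibration by stroke-volume matching, and the
simulated-vs-experimental comparison stage.

## Synthetic mock-loop data

The generators produce every input the analysis consumes, each with a
recorded ground truth, so extraction error is measured rather than assumed.

* **Pressures.** The transvalvular pressure difference Δp(t) over one cycle
  is a parametric template: a half-sine systolic hump of peak `dp_peak` over
  `systolic_fraction·T`, a short (2 % of T) linear blend, then a constant
  negative diastolic plateau `diastolic_dp`. A half-sine has mean 2/π·peak
  over its positive lobe, so the default `dp_peak = 69 mmHg` gives a mean
  systolic drop of ≈ 44 mmHg — the baseline (d0, 75 bpm, 3.2 L/min)
  operating point; `systolic_fraction = 0.35` puts the ejection time in the
  physiological range. The aortic trace is a smooth template around
  80 mmHg; the LV trace is the aortic trace plus Δp. Noise is per-sample
  i.i.d. Gaussian with sd `noise_sd·dp_peak`, seeded.
* **Flow.** A quasi-static orifice (Bernoulli) law
  Q = C_d·A·√(2·max(Δp,0)/ρ) with water density, giving closed-form signal
  statistics. This is test scaffolding, not a claim about the bench loop:
  it has no inertance, no compliance and no phase lag, so passing tests
  show the *statistics pipeline* is correct, not that the generator is
  haemodynamically faithful. The trace is rescaled so the positive-phase
  integral equals CO/HR, and a half-sine pump-return lobe with trapezoidal
  integral exactly −5 mL (the bench protocol's return volume) is inserted
  in the longest zero-flow window.
* **Endoscope frames.** A dark multi-lobed orifice (boundary
  r(θ) = r₀(1 + 0.25 cos 3θ), area πr₀²(1 + 0.25²/2)) on bright leaflet
  tissue inside the valve-housing circle, rasterized at 4× supersampling
  and averaged down; the supersampled pixel count is stored as the
  per-frame true area (within 2 % of the analytic area at ≥ 200 px valve
  radius). The orifice is dark because the camera looks through the
  opening into the unlit ventricular side; the extraction pipeline inverts
  the image accordingly.
* **Leaflet clouds.** Points on a jittered structured polar grid covering
  the annular leaflet region between the orifice boundary and the housing
  radius (default 1.9 cm), bellied axially so the cloud is genuinely 3D,
  labelled 1–3 by angular sector with a 5 % calcified flag. The default
  60 000 points keep the projected occupancy closed around the orifice at
  the 150×150 raster; fewer than 5 000 points is rejected.

## Signal statistics

Cycle segmentation cuts consecutive windows of length T from a supplied
start index (an optional RMS-based periodicity detector is provided; the
experimental criterion is visual, so the caller decides). All integrals
are trapezoidal; threshold crossings are located by linear interpolation
between samples, an exact zero counting as a crossing. The ejection window
runs from the first upward pLV > pAO crossing to the first subsequent
negative flow sample; if the flow never becomes negative (possible with
the synthetic orifice law) the window falls back to the downward zero
crossing of Δp. Qmean and stroke volume are the windowed mean and
integral; Δp_mean averages Δp over its contiguous positive region per
cycle; inter-cycle statistics use the sample (ddof = 1) standard
deviation; measurement-uncertainty bounds are value·(1 ∓ frac) with
frac = 0.10 (flow-probe uncertainty).

## Valve area from frames and clouds

Frames: greyscale → invert → min–max normalise → fixed threshold → hole
filling → removal of components below `min_object_px` → morphological
closing → circular housing mask → the two largest 8-connected components,
converted by n_px/px_per_cm². The threshold is the dominant uncertainty,
so the extraction is repeated at 110 % and 90 % of it (lower and upper
area limits on the inverted image). When no fixed threshold is supplied,
Otsu's threshold of the brightest frame is used for the whole stack — a
stated default, not a claim about the reference analysis.

Clouds: orthogonal projection along the valve axis (in-plane basis from
two cross products; default axis is the cloud's stored axis), occupancy
raster with half-open cells (default 150×150 over a 4 cm extent), hole
fill, and the largest 8-connected component of (filled − original)
converted by the cell area. The raster resolution is the dominant
uncertainty; the area is re-evaluated at 110 % and 90 % of the resolution
and the pair is reported as an explicitly ordered (min, max) envelope:
with a dense cloud the coarser grid swallows more of the hole boundary and
yields the smaller area, so a fixed resolution→limit assignment would
invert the band. Boundary cells that contain any leaflet point count as
occupied, so the nominal estimate is biased low by roughly half a cell
ring (≈ 5–8 % for a 0.5 cm² orifice at the default raster).

## 2D partitioned FSI solver

The numerical scheme is dimension-agnostic and is exercised here on a
plane channel (8 × 2 cm) with a flexible leaflet; the 3D patient-specific
geometry, re-meshing and mortar contact are out of scope.

**Fluid.** Incompressible Navier–Stokes with ALE convection
(u_L − u_m)·∇u, u_L = 2uⁿ − uⁿ⁻¹, on P1 triangles, advanced by a BDF2
fractional step: predictor solve
(M + (2/3)Δt(νK + C))u* = M(2uⁿ − ½uⁿ⁻¹) − (Δt/ρ)Gpⁿ, pressure Poisson
for pⁿ⁺¹ − pⁿ, correction (3/2)uⁿ⁺¹ = u* + (Δt/ρ)G(pⁿ − pⁿ⁺¹). The
predictor unknown u* carries the 3/2 BDF2 scaling (the correction divides
it out), so the implicit viscous/convective operator must act on
(2/3)u* = uⁿ⁺¹ — applying it to u* directly equilibrates steady flows at
2/3 of the true profile. For the same reason Dirichlet velocity data is
imposed on u* at 3/2 of its physical value and re-imposed exactly after
the correction.

The pressure operator is the discrete projection operator Gᵀdiag(M)⁻¹G
(G the weak gradient restricted to free velocity dofs), which makes the
corrected velocity exactly discretely divergence-free on fixed meshes.
Equal-order P1/P1 pairs carry chequerboard pressure modes; in coupled
stepping the operator is blended with the consistent P1 Laplacian,
A ← (1−θ)A + θK with θ = 0.15 — the defect K − A is O(h²) on smooth
modes and O(1) on the chequerboard, so this is a consistent
stabilisation (a documented replacement for the orthogonal-subscale
stabilisation of the reference solver, whose parameters are not public).
On fixed meshes θ = 0 (exact projection). Pressure/velocity
sub-iterations (≤ 10) drive the residual toward the projection tolerance.
Pressure nodes whose entire velocity patch is Dirichlet (the corner where
the leaflet meets the wall) carry no divergence control and have their
increment pinned to zero. Where the boundary moves, the weak boundary
flux of the prescribed interface velocity is subtracted from the Poisson
residual — the interior divergence must balance the boundary flux, not
vanish.

Dirichlet data: Δp(t) at the inflow and 0 at the outflow for the
pressure; no-slip walls and the interface velocity on the leaflet for the
velocity; zero normal pressure gradient elsewhere. A Smagorinsky eddy
viscosity ν_t = (C_sΔ)²|S| (C_s = 0.18) is available but off by default:
the desk-scale benchmark is laminar, and the LES-quality (Pope) check
(3/2)·C·(Δ/(πL))^(2/3) is exposed regardless.

**Solid.** Compressible neo-Hookean plane strain,
W = G/2(tr C − 2 − 2 ln J) + λ/2(ln J)², P1 triangles, implicit Newmark
with γ = 0.6, β = 0.4 (γ > ½ ⇒ algorithmic damping; energy decay is
asserted in the tests), full Newton with the analytic material+geometric
tangent, lumped mass. Clamped boundary: the leaflet base.

**Coupling.** Per time step, a fixed-point loop: fluid solve with the
current interface velocity → interface traction (−pI + μ(∇u + ∇uᵀ))·n_s
integrated over interface edges → implicit Newmark solid step → Aitken
dynamic relaxation of the displacement increment → optional golden-section
line search (≤ 8 evaluations) on the increment scale s ∈ [0, 1]
minimising the out-of-balance force of the time-discrete system (inertia
included) → ALE mesh update (linear elasticity on the reference
configuration, interface Dirichlet data, outer boundaries fixed) →
convergence when the normalised interface-displacement change drops below
ε = 10⁻⁴ (with an absolute floor of 0.1 nm/node so the rigid limit
terminates). The interface fluid velocity is the discrete (uₛ − uₛⁿ)/Δt,
consistent with the mesh velocity measured against the time-n
configuration; using the Newmark velocity instead (γ/β-weighted) leaves a
~50 % inconsistent boundary flux that the projection cannot balance.
Aitken relaxation is the added-mass control: at density ratio 1 the bare
exchange diverges geometrically. The reference solver's pressure-matrix
augmentation with interface solid contributions is implemented
(`CouplingConfig.added_mass`, compliance ρ_f ℓ²/m_s on interface rows)
but is off by default — it deliberately relaxes incompressibility near
the interface and measurably biases the through-flow at desk scale.

**Contact.** None: closure is limited by a minimum-gap stop (tip keeps
≥ 2 % of the channel height) so the fluid mesh cannot degenerate; the
reference 3D mortar-contact parameters are recorded in the configuration
for documentation only. Mesh inversion aborts the run with a diagnostic
(re-meshing is out of scope); partial traces are returned with a failure
status.

**Benchmark geometry and regime.** The flap is a staircase beam leaning
one grid column per row (thickness 2 cells), clamped at the bottom wall,
tip at 75 % of the channel height. The lean matters: bending then lowers
the tip and opens the gap at first order in the rotation, so the stroke
volume is monotone decreasing in the shear modulus with usable
sensitivity, which the calibration requires; a vertical cantilever opens
the same gap only at second order. The default bench regime is laminar
(water density, μ = 0.1 Pa·s, driving pulses of a few hundred Pa);
the reference time step 2·10⁻⁴ s is the configuration default, while the
test suite runs the benchmark at Δt = 10⁻³ s with 50–60 ms pulses —
self-consistent checks (calibration recovery, rigid limit, mass
conservation) are invariant to that choice. A time-step-sensitivity
diagnostic (mean flow at Δt vs Δt/2) is produced by
`timestep_sensitivity`.

## Calibration

Stroke volume is monotone decreasing in the leaflet shear modulus over
the physical bracket (stiffer valve → smaller opening), so the
calibration is a bracketed root search on SV(G) − SV_target: bisection
with a secant proposal accepted only well inside the bracket, every
forward evaluation logged, ≤ 12 evaluations at the default tolerance.
Violated monotonicity (checked at the bracket endpoints) and an
out-of-bracket target are errors, not silent extrapolation. The
two-material (calcified) leaflet support assigns the stiff regions the
tissue density and a Poisson ratio solving
K(G_c, ν_c) = K(G_t, ν_t) with K = 2G(1+ν)/(3(1−2ν)) — the bulk-modulus
match that volume-averaged element formulations require; the solution is
the exact ν_c = (3K − 2G_c)/(6K + 2G_c). Cross-validation calibrates on
one flow condition and evaluates the remaining ones with the calibrated
modulus, reporting relative errors and 10 %-uncertainty flags.

## Verification reporting

The summary table holds, per valve model (non-calcified/calcified) and
dobutamine condition (d0–d20), the cycle time, mean transvalvular
pressure drop, experimental and simulated mean flow (with measurement
uncertainty / inter-cycle sd) and AVA (with range bounds). Errors are
symmetric percent differences 100·|sim − exp|/((sim + exp)/2); the
denominator is configurable (`exp`, `sim`, `mean`) because reporting
conventions differ and the choice moves group means by up to half a
percentage point; the symmetric form is the default. Group summaries
average the four conditions and round once, at the summary level.
Within-uncertainty flags compare |sim − exp| against 10 % of the
experimental value. The packaged table stores the d5 cycle time as
tabulated (0.76 s) although the simulation protocol lists 0.75 s; the
fixture comment flags the discrepancy rather than resolving it.

## Known limitations

* The synthetic loop has no Windkessel dynamics; flow and pressure are
  related quasi-statically, so waveform-shape fidelity is out of scope.
* The 2D benchmark is laminar and desk-sized; no turbulence-resolving
  claims are made (the Pope check is reported for the reference
  configuration, not for the benchmark).
* P1/P1 equal-order elements need the documented pressure stabilisation
  in coupled stepping; the residual divergence there is bounded but not
  machine-zero.
* The leaflet cannot coapt (no contact); diastolic behaviour below the
  minimum-gap stop is not modelled.
* The point-cloud area estimate is biased low by boundary-cell occupancy
  at the default raster; the resolution envelope brackets but does not
  remove the bias.
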