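# Methods

## The two-layer elasto-visco-plastic model

Bone tissue loaded in tension shows, superposed in a single stress–strain
record, linear elasticity, strain-rate-dependent (viscous) stiffening, and
post-yield hardening. `bonerheo` separates these contributions with a
one-dimensional rheological model of two parallel layers sharing the global
engineering strain ε(t):

* a **Prandtl layer** — a spring `E_pr` in series with a frictional slider.
  The layer stress is `σ_pr = E_pr (ε − ε_p)`. The slider admits stress
  states with `f(σ_pr, α) = |σ_pr| − k(α) ≤ 0`, where the yield limit
  hardens with the equivalent plastic strain α by Voce exponential
  saturation, `k(α) = σ_Y + (σ_u − σ_Y)(1 − e^{−pα})`. Plastic flow obeys
  the Kuhn–Tucker complementarity and consistency conditions: flow occurs
  only on the yield surface and the stress persists on it during flow.
* a **Maxwell layer** — a spring `E_mx` in series with a dashpot η, with
  `σ̇_mx + (E_mx/η) σ_mx = E_mx ε̇` and damper strain
  `ε_v = ε − σ_mx / E_mx`.

The total model stress is `σ_mod = σ_pr + σ_mx`. In the elastic range the
model is a Zener solid (standard linear solid), which gives closed forms for
the storage modulus E′, loss modulus E″ and loss tangent tan δ, and the
modulus bounds: quasi-static stiffness `E_pr`, instantaneous stiffness
`E_pr + E_mx`. Any apparent modulus read off a finite-rate test lies between
the two.

Assumptions: geometrically linear kinematics (engineering stress/strain),
no damage (stiffness degradation at the plastic strains of interest is below
one percent for single trabeculae), symmetric tension/compression response,
isothermal conditions.

### Parameters

| symbol | meaning | unit | search range |
|--------|---------------------------------|-------|--------------|
| E_pr | Prandtl spring (long-term) modulus | MPa | 500–5000 |
| σ_Y | yield stress | MPa | 10–100 |
| σ_u | ultimate (saturation) stress | MPa | σ_Y+10 – σ_Y+100 |
| p | hardening exponent | – | 10–1000 |
| E_mx | Maxwell spring modulus | MPa | 500–5000 |
| η | dashpot viscosity | MPa·s | 2000–20000 |

## Numerics

**Prandtl layer.** Backward-Euler elastic-predictor / plastic-corrector
(return mapping). The trial stress `σ_tr = E_pr(ε_{n+1} − ε_{p,n})` is
accepted if admissible; otherwise the plastic multiplier increment Δγ solves
the discrete consistency condition `|σ_tr| − E_pr Δγ − k(α_n + Δγ) = 0`
(closed form for perfect/linear hardening; for Voce, a bisection-safeguarded
Newton iteration on the bracket `(0, f/E_pr]`, residual tolerance
`10⁻¹⁰ σ_Y`, with a bracket-collapse stop for very steep hardening where the
residual tolerance is below float resolution; at most 100 iterations). The
scheme is unconditionally stable and step-size errors vanish for the
protocol's piecewise-linear loading between the consistency solves.

**Maxwell layer.** The exponential integrator
`σ_{n+1} = σ_n e^{−Δt/τ} + η ε̇_n (1 − e^{−Δt/τ})`, τ = η/E_mx, which is
*exact* for piecewise-linear strain — the form the loading protocol and the
1 Hz-resampled measurements actually have.

Both loops are numba-compiled; a simulation of the 208-sample protocol costs
microseconds, which is what makes the multi-start identification cheap.

**Degenerate inputs.** Non-monotone or duplicated time stamps and NaNs are
rejected, never silently repaired. `E_mx = η = 0` (or a disabled Maxwell
flag) yields zero viscous stress; one of the two being zero alone is an
error, as is a degenerate Zener evaluation. Initial internal state
(ε_p, α, σ_mx) defaults to zero and can be supplied for chained runs.

## Loading protocol and objective

The displacement-controlled protocol (rate 0.01 mm/s) is: ramp to 0.025 mm,
hold 60 s, ramp to 0, hold 60 s; then cycles of +0.05 mm ramp, 10 s hold,
−0.025 mm unload, 10 s hold. The part-1 ramp counts as loading cycle 1 and
the profile is truncated at the end of the hold after the 4th cycle's unload
(207.5 s; held peaks 0.025/0.05/0.075/0.10 mm). Signals are built at 10 Hz
(the camera rate) and resampled to 1 Hz; corner instants are snapped into
the coarse grid so corner values and weights survive resampling exactly.

The identification objective is the corner-weighted RMSE
`RMSE_w = sqrt(n⁻¹ Σ w_i (σ_mod(t_i) − σ_exp(t_i))²)` with `w_i = 1` at
every ramp↔hold transition (16 points for the default profile; t = 0 is
never weighted) and `w_i = 0` elsewhere; n is the total sample count.
Weighting every sample instead reduces it to the plain RMSE, which is also
reported at the optimum for interpretability.

Preload handling: measured force converts to stress by `σ = F/A_mean`; both
stress and displacement are shifted to zero at t = 0 and the removed offset
is kept as the specimen prestress, which is added back onto the identified
σ_Y and σ_u afterwards (additive convention; the alternative — refitting on
offset data — is not what the shifted-data pipeline implies).

## Multi-start identification

Nelder–Mead downhill simplex from every point of a Cartesian grid over the
search box (4 points per parameter including endpoints ⇒ 4⁶ = 4096 starts;
desk-scale runs use 2 points ⇒ 64). Positivity and σ_u ≥ σ_Y are enforced
structurally: the optimizer works on log-transformed internal coordinates
(E_pr, σ_Y, Δ, p, E_mx, η) with Δ = σ_u − σ_Y, so no penalty walls distort
the simplex. Default stopping: `fatol = 10⁻³` MPa on the objective,
`xatol = 10⁻³` on the transformed parameters, 2000 iterations per start.
The best local solution (ties broken by lowest start index, so the outcome
is independent of execution order) is polished by up to three simplex
restarts from the incumbent. Individual start failures are recorded, not
fatal. Everything is deterministic: identical inputs give bit-identical
results.

A linear-hardening ablation fit (`fit_linear_hardening`) optimizes
(E_pr, σ_Y, H, E_mx, η) the same way, with the hardening coefficient H
searched over 100–10 000 MPa; it exists to quantify how replacing Voce
saturation by linear growth degrades the fit.

## Synthetic specimens

No tensile records are shipped; the `synthetic` module generates them. Each
specimen, reproducible from `(master_seed, index)`:

1. draws a **gauge factor** (strain of the optical gauge length per mm of
   machine displacement) from a lognormal calibrated so the first-ramp
   strain rate scatters like the measured cohort (0.00196 ± 0.0018 1/s; the
   scatter stands in for varying trabecular sizes and shapes);
2. draws **true parameters uniformly in the search box** (log-uniform
   optional), rejecting draws until the noise-free response (a) accumulates
   at least 0.5 % equivalent plastic strain (scaled down proportionally for
   small-amplitude specimens, whose achievable plastic strain is
   geometrically limited) and (b) peaks within 17.4–123.4 MPa, the ±2 SD
   band of the apparent maximum stress at which the real specimens failed
   (70.4 ± 26.5 MPa). Both conditions emulate the retained experimental cohort —
   every specimen was loaded measurably beyond yield and up to
   fracture-level stresses. The rejection runs conditionally on the drawn
   gauge factor so the strain-rate statistics are preserved; a gauge factor
   admitting no yielding box parameters is redrawn.
3. draws a **prestress** lognormal matched to the reported 5.52 ± 3.35 MPa;
   the cross-section follows as `A_mean = preload/prestress` (0.05 N
   preload), since the real per-specimen areas are not tabulated;
4. simulates the stress response, adds the prestress, applies the same
   zero-shift as measured data, and adds i.i.d. Gaussian stress noise
   (default SD 3 MPa, the scale of the reported fit error).

What the generator does **not** emulate: model–reality mismatch (its noise
is white, whereas real residuals are structured), damage and fracture,
DIC/image artefacts, machine compliance, temperature drift, and any
correlation between material constants and specimen geometry beyond the
rejection conditioning. Passing recovery tests therefore demonstrate that
the estimator inverts its own forward model under realistic noise and
loading — not that the model is an adequate description of real bone.

## Parameter identifiability

Recovery experiments (15 specimens, noise SD 1 MPa, 2-point start grid; run
by `scripts/acceptance.py` and the test suite) recover E_pr with a median
error of a few percent. σ_Y recovers with a median error on the order of
10 %, and the exact figure is cohort-seed-dependent: with 1 MPa noise
observed only at 16 corner points, specimens whose yield knee falls between
corners admit σ_Y–p–Δ trade-offs whose global objective minimum sits away
from the truth — the optimizer routinely finds objectives *below* the
truth's, so this is an information limit of the experiment, not an
optimization defect (a noise-free specimen is recovered essentially
exactly; see the fixed-point test). E_mx and η carry wider spread,
matching the objective's sensitivity ordering (most sensitive to E_pr and
σ_Y, least to η and E_mx). p is the weakest-identified parameter whenever
post-yield strain is modest.

## Apparent properties

The apparent Young's modulus uses the R²-window method: windows anchored at
the ramp's first sample grow from 5 points; the window maximizing R²
(largest window on ties, with a 10⁻¹² tolerance against rounding) defines
the linear region and its least-squares slope is E_app. On noise-free model
ramps E_app always lies in `[E_pr, E_pr + E_mx]` and grows with strain
rate.

The rate sweep reports an apparent yield stress per curve. The classical
0.2 %-offset construction (also provided, `offset_yield_stress`) uses the
curve's own initial slope; because that slope itself grows with rate, the
offset intersection is provably non-monotone across the viscous transition
band on model data. The sweep therefore uses the **kink stress** — the
stress at the point of maximum curvature — whose quasi-static limit is σ_Y
and which inherits monotonicity from the pointwise ordering of
constant-rate curves. This is a deliberate design choice for noise-free
model curves; curvature maxima are not robust on noisy measured data.

## Problem sizes and defaults

Desk-scale defaults keep every experiment cheap while preserving the
experiments' structure: the 1 Hz protocol (208 samples), 2-point start grids (64 starts)
for recovery experiments, cohorts of 15 (the emulated cohort size), 5 random parameter
sets for oracle and Zener cross-checks, and 8000-fold step refinement for
the explicit reference integrations. The full 4-point grid (4096 starts per
specimen) is supported and simply scales the same machinery.

## Known limitations

* Small-strain theory only; at 9 % strain engineering stress underestimates
  true stress by ~4 % (ν = 0.25) and logarithmic strain reads 8.6 %.
* Uniqueness of the identified optimum is not certified; the multi-start
  sweep reduces, but cannot eliminate, the risk of distant near-equivalent
  minima (see identifiability above).
* The loss tangent of a cohort is the average of per-specimen loss
  tangents; evaluating the closed form at cohort-average parameters gives a
  systematically different (here lower) number.
* No damage mechanics: repeated deep post-yield cycling of real bone would
  violate the constant-stiffness assumption.
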