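# Methods

This note records the models, the numerical choices, and the reasoning
behind defaults, in enough detail to re-derive the implementation.

## Fiber model: standard linear solid

The microfiber is a three-element standard linear solid: spring `K₂` in
parallel with a Maxwell arm (spring `K₁` + dashpot `η`).  In
force/elongation form, a step elongation `u₀` (μm) produces

    F(t) = (λ₁ + λ₂ e^(−t/τ)) u₀        [μN]

with `λ₁ = S K₂ / L₀`, `λ₂ = S K₁ / L₀` (μN/μm) and `τ = η / K₁` (s).
The built-in parameter sets are the fitted values for 7% w/v GelMA
(λ₁ = 11.23, λ₂ = 0.7629, τ = 44.94, step u₀ = 9 μm) and 5.5% w/v
(λ₁ = 30.72, λ₂ = 3.584, τ = 56.20).

As a transfer function from elongation to force,

    G(s) = ((λ₁+λ₂) s + λ₁/τ) / (s + 1/τ),

a single pole at −1/τ with instantaneous gain λ₁+λ₂ and DC gain λ₁.  The
state-space realization is **re-derived from this transfer function**
(plant state `x_p`, feedthrough λ₁+λ₂) and augmented with the integral
tracking state `e_yI = ∫(F_f − F_cmd) dt`:

    A = [[0, 1], [0, −1/τ]],  B = [λ₁+λ₂, −λ₂/τ],  B_ref = [−1, 0],
    C = I₂,                   D = [0, λ₁+λ₂].

Correctness is defined solely by behavior: the realization's step
response must reproduce the relaxation closed form (tested to
< 10⁻⁶ μN over 1000 grid points), its DC and instantaneous gains must be
λ₁ and λ₁+λ₂, and an independent transfer-function realization must give
identical input–output traces.

Open-loop integration uses fixed-step RK4 at `dt = τ/100` by default,
with exact matrix-exponential (ZOH) discretization available for
verification; steps coarser than τ/20 warn and coarser than τ/5 are
refused.

### Relaxation fitting

`fit_sls` is a bounded nonlinear least-squares fit (scipy `curve_fit`)
of the relaxation closed form, seeded from the data (tail → λ₁, head
minus tail → λ₂, a third of the span → τ).  When the fitted λ₂ falls
below 10⁻³ λ₁ there is no measurable relaxation and τ is flagged
unidentifiable rather than reported.  With additive noise of 1% of F(0),
the relaxing component of the 7% curve (λ₂/λ₁ ≈ 6.8% of the signal)
gives a theoretical R² near 0.73 — parameter recovery is nevertheless
excellent (λ₁ to ~0.1%); recovering τ to 2% (median) requires sampling
around 20 Hz, the frame rate a vision system records at, which is what
the synthetic relaxation tests use.

## Force controller

The control problem: make the vision-derived fiber force `F_f` track
`F_cmd = 5 sin(2π·0.01·t) + 5` μN although the plant parameters vary
with GelMA concentration.  Architecture (all gains designed on the
*nominal* model):

1. **LQR baseline** on the augmented plant, `Q = diag(10, 1)`, `R = 1`.
   The heavy weight on the integral state gives tight tracking at the
   slow command frequency.
2. **Observer gain** `L_obs` (2×2, both outputs `e_yI` and `F_f` are
   available) by pole placement at 5× and 6× the plant's relaxation
   pole, i.e. {−5/τ, −6/τ}.  Slightly distinct poles keep the placement
   well-conditioned.
3. **Observer-like reference model.**  The reference state `x_ro`
   evolves closed on the baseline law only:

       dx_ro/dt = A_ref x_ro + B_ref F_cmd + L_obs y,
       A_ref = A − L_obs C − (B − L_obs D) K_xᵀ,

   with `y` the measured outputs.  This is essential: if instead the
   observer is driven by the *total* applied input (baseline plus
   adaptive), the adaptive input cancels out of the state-error
   dynamics, the adaptation integrates open-loop, and the weights drift
   without bound.  With the reference model closed on the baseline law,
   `u_ad` enters the error dynamics through `+(B − L_obs D)` and the
   Lyapunov argument goes through.
4. **Adaptive augmentation** `u_ad = Θ̂ᵀ Φ(x_ro)` with
   `Φ = [1, T₁..T₃(x̂₁), T₁..T₃(x̂₂)]`, Chebyshev polynomials of the
   reference state normalized to [−1, 1] by a running min/max.  The law

       dΘ̂/dt = −Γ (Φ · e_xᵀ P_ref (B − L_obs D) + σ_leak Θ̂),

   with `e_x = x̄ − x_ro` (true minus reference state) and `P_ref` the
   SPD solution of `A_refᵀP + P A_ref = −Q_ref`, `Q_ref = I`.  The
   minus sign is what completing the square in dV/dt of
   `V = e_xᵀ P_ref e_x + tr(Θ̃ᵀ Γ⁻¹ Θ̃)` requires given that `u_ad`
   enters the error dynamics with `+(B − L_obs D)`; the opposite sign is
   exponentially destabilizing (verified numerically).

**Adaptation-rate scale.**  Because `A_ref` inherits the plant's slow
modes, `P_ref` has entries of order 10⁴ and `e_xᵀ P_ref (B − L_obs D)`
of order 10²–10³ per unit error.  A raw `Γ = I` therefore corresponds to
an absurdly fast adaptation that bursts under measurement noise; the
default is `Γ = 10⁻³ I` (effective Lyapunov-gradient gain of order ten)
plus a light σ-modification leak `σ_leak = 0.01 s⁻¹` that bounds the
weights under persistent noise without visibly slowing adaptation.  Both
are configuration keys (`controller.gamma`, `controller.leak_sigma`).

**Sampled-loop step size.**  The feedthrough path closes a fast loop
with a pole near `−(λ₁+λ₂)_true · K_x[0]` (≈ −38 s⁻¹ for the 7% fiber,
≈ −109 s⁻¹ for the stiffer 5.5% fiber under the same controller).  A
zero-order-hold loop is only stable, and only noise-benign, when
`ρ·dt ≪ 1`; the simulator therefore caps the default step at
`dt = min(τ/100, period/200, 0.2/ρ)` with ρ the spectral radius of the
ideal closed loop *on the true plant*.  Within each step the reference
model is propagated by its exact ZOH solution, the scalar plant pole by
its exact exponential, the integral state by Euler on the sampled
measurement, and the adaptive weights by explicit Euler (adaptation is
slow relative to the loop).

**Noise model.**  The only stated property of the measurement noise is
its mean magnitude, 0.277 μN.  The default is zero-mean Gaussian with
E|n| = 0.277 μN (σ = 0.277·√(π/2) ≈ 0.347 μN); a zero-mean uniform
variant sits behind the same interface.  A DC offset would bias the
integral action and break the symmetry of the observed tracking errors,
so nonzero-mean interpretations are excluded.  Noise corrupts only the
*measured* channel (`F_meas`, and the tip deflection `u_tip` derived
from it); the physical force on the fiber (`F_f` in the trace) is the
controlled quantity, and the < 1 μN tracking bound applies to it.  This
reading is forced by the statistics: the Gaussian tail of the
measurement noise alone exceeds 1 μN within a few hundred samples, so no
controller could keep the *measured* maximum error under 1 μN.

**Performance** (defaults, seed-averaged): maximum steady-state error
≈ 0.48–0.61 μN on both the matched 7% fiber and the mismatched 5.5%
fiber; with the adaptive term disabled the steady-state RMS error on the
mismatched fiber is consistently larger.  The phase delay between
command and response visible in the traces is left uncompensated — it is
part of what the downstream sinusoid fits measure.

In the simulation `e_x` uses the true plant state, which a physical rig
cannot measure; this is the usual simulation-side shortcut and is the
reason the Lyapunov decrease test runs on simulated trajectories only.

## Sensing tube and vision

The sensing tube is an Euler–Bernoulli cantilever; deflections are
stored as magnitudes with direction flagged separately, since every
downstream formula uses magnitudes.  Calibration against a reference
scale measures the local stiffness `K_a = F/u_a` at the touch point
`x_a`, refers it to the tip via the geometric factor `2x_a/(3L − x_a)`
(which is 1 at `x_a = L`), and fits the single-parameter family
`K(x_a) = 6a/(3L x_a² − x_a³)`; `a` coincides with the flexural rigidity
`E_t I_z` when the data follow the beam model exactly.  Units are SI
internally and μN/μm/mm at the API boundary.

Tip detection: Otsu threshold (dark tube on bright field), one round of
3×3 binary dilation to suppress speckle, Harris corners (k = 0.04),
then the corner of maximal x on the largest dark component — the free
end of a horizontal tube is its rightmost feature; ties within one
pixel column break by Harris response.  The synthetic renderer draws
the tube band so that the requested tip pixel is its upper-right
corner; the render→detect round trip stays within 2 px at 5%-of-range
pixel noise.  The tip-jitter model converts a pixel-level standard
deviation (e.g. the 2.619 px figure obtained from a Bessel-corrected
sample estimate) to microns via the optics (2.2 μm/px through a 4×·0.5×
objective).  Multiplying σ_px by μm/px gives ±5.76 μm of deflection
jitter; the package deliberately does not reproduce any smaller printed
uncertainty figure whose derivation it cannot state.

## Stress–strain analysis

Stress `σ = F_f/S` (1 μN/μm² = 10³ kPa), strain `ε = (L_m − u_tip)/L₀`
with the approximation `ε ≈ L_m/L₀` available behind a flag.  Sinusoid
fits are linear in (sin, cos, const) at a known frequency; with the
frequency free, the periodogram peak (parabolically interpolated) seeds
a nonlinear refinement.  Constant signals are rejected as degenerate
rather than fitted.

For pure fitted sinusoids the crossover-point and maximum-strain
constructions on the Lissajous ellipse coincide: in
amplitude-normalized coordinates the loop is symmetric about the
diagonal, so the long-axis endpoint projections satisfy
`L_y/L_x = σ₀/ε₀` exactly.  The implementation computes `E_c = σ₀/ε₀`
and retains the numerical long-axis construction as a cross-check
(asserted to 10⁻⁶ relative).  Loop area is `π σ₀ ε₀ |sin(δ−φ)|`,
verified against the numerically integrated ∮σ dε to < 0.1%.

**Dissipation vs frequency.**  The SLS loss tangent peaks at ωτ ≈ 1 —
about 0.0035 Hz for the 7% parameters.  Below that corner the loop area
grows with frequency; above it, it shrinks.  The frequency-ordering
analysis therefore applies below the corner, and the tests exercise it
at 0.001–0.003 Hz.  At the 0.005–0.02 Hz band used for the
modulus-invariance sweeps the *measured E_c* is nearly constant (that is
the point of the method), but the dissipation ordering is inverted for
an SLS fiber — a genuine model prediction worth knowing when comparing
against real fibers, whose dissipation may still grow in that band.

**Ramp comparison.**  The constant-rate ramp (default 10 mm/min tube
speed, 0.2 s sampling) yields `E_cf` as the OLS slope of σ on ε.  During
a ramp the SLS slope decays from λ₁+λ₂ toward λ₁ with time constant τ,
so a fit window that extends into the relaxing tail under-reports the
modulus; the prefix-window sensitivity report (slope on the first 2, 3,
…, n samples) reproduces this ordering.  On matched windows (ramp
duration ≈ τ/2) `E_cf` agrees with the cyclic `E_c` within 5%.

## Synthetic study conditions

Defaults throughout are the study conditions: command
`5 sin(2π·0.01·t)+5` μN for 3 cycles, noise E|n| = 0.277 μN, Table
presets for the two fiber types, fiber diameter 150 μm with a 1 mm gauge
length, camera 1600×1200 over 7.04×5.28 mm with objective factor 2, and
tip jitter 2.619 px where pixel noise is needed.

The sensing-tube stiffness is never printed for the real rig; the
simulator's default is K = 5 μN/μm.  The choice matters for the strain
channel: the measured tip deflection `u_tip = F_meas/K` carries the
vision noise into `ε = (L_m − u_tip)/L₀`, and for the (stiff) preset
fibers a very soft tube (K ≈ 0.5 μN/μm) would make that leaked noise as
large as the elongation signal itself.  K = 5 keeps the strain
signal-to-noise around 6:1 so that phase lags of a few hundredths of a
radian are resolvable over a 3-cycle fit.  Force-side results (tracking
errors) are independent of K.

What the generator does *not* emulate: actuator quantization and
backlash, fluid drag on the tube, nonlinear (large-strain)
viscoelasticity, multi-exponential relaxation, photobleaching or
illumination drift in the images, and fiber-to-fiber variability.
Passing tests therefore demonstrate the correctness and robustness of
the *method* — controller, estimator, and analysis chain — under the
stated conditions, not the accuracy of any particular real-fiber
modulus value.  Experimental moduli of real microfibers, the rig's
calibration R², and all cell-culture observations require the physical
system and are out of scope.

## Numerical details and degenerate inputs

- Lyapunov/Riccati solves via `scipy.linalg`; residuals asserted at
  10⁻⁹/10⁻⁸.  Observer placement refuses unobservable pairs and names
  the deficient mode direction.
- `build_reference_model` refuses a non-Hurwitz `A_ref` (the design must
  be redone) — reachable only with pathological gain choices.
- Closed-loop divergence (|F_f| above 100× the command scale or
  non-finite) aborts with an `UnstableLoopError` naming the time of
  failure; the CLI maps it to a nonzero exit.
- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical traces and images.
- Phases are wrapped to (−π, π]; amplitude signs are normalized into the
  phase.
- Zero-force, zero-deflection, blank-image, constant-signal and
  single-position-calibration inputs all return explicit errors or
  flags, never silent defaults.
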