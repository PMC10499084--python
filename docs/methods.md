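# Methods

`indentml` identifies hyperelastic material parameters from spherical
nano-indentation load–displacement curves. This note records the models,
the synthetic-data generator, the learning setup, the inversion
algorithms, and the numerical choices, together with what the bundled
validation does and does not demonstrate.

## The problem

A rigid spherical probe of radius `R` is pressed a depth `δ` into a soft
block of lateral size `W` and thickness `H`, and the reaction force
`F(δ)` is recorded up to `δ = R/2`. The task is the inverse problem:
given `F(δ)` and the sample geometry, recover the parameters of a
constitutive model of the material. Two quasi-incompressible isotropic
models are supported:

* **neo-Hookean** — `W = (μ/2)(Ĩ₁ − 3) + (K/2)(ln J)²`, one parameter,
  the shear modulus `μ`;
* **Gent** — `W = −(μ J_m/2) ln(1 − (Ĩ₁ − 3)/J_m) + (K/2)(ln J)²`, which
  adds the stiffening limit `J_m`: the energy diverges as the first
  deviatoric invariant excess approaches `J_m`, capturing the strain
  stiffening of soft tissue. Small `J_m` means strong stiffening;
  `J_m → ∞` recovers neo-Hookean behaviour.

Here `Ĩ₁` is the first invariant of the isochoric Cauchy–Green tensor and
`J` the determinant of the deformation gradient. Quasi-incompressibility
is enforced by `K = 1000 μ` by default (configurable). The `(K/2)(ln J)²`
volumetric form is one of several common penalties; at `K/μ = 10³` the
choice affects energies only at the 10⁻³ level.

The classical interpretation route fits the Hertzian law
`F = (16/3) μ √R δ^{3/2}` (rigid sphere, incompressible half-space). It
assumes shallow indentation of a laterally infinite, thick, linear
sample — all violated for small soft-tissue specimens indented to
`δ = R/2`, which is what motivates the learned inversion.

## Synthetic ground truth

Training data come from a semi-analytic surrogate for the nonlinear
finite-element solution of the block-indentation problem (decks for an
external FE solver can be emitted instead; see below). The surrogate is
a multiplicatively corrected Hertz model in `x = δ/R`:

    F(x) = (16/3) μ R² x^{3/2} · c_depth(x) · c_thick(χ_H) · c_width · g(x, J_m)

* `c_depth(x) = 1 + 0.15 x` — net large-depth deviation from Hertz. Two
  effects compete at deep indentation: the exact spherical (rather than
  paraboloidal) profile softens the response — a cubic fit of the exact
  rigid-sphere solution gives about `1 − 0.100 x` — while finite-strain
  stiffening of the quasi-incompressible material (contact strains reach
  tens of percent at `x = 0.5`) more than compensates, for a net
  `+0.15 x`. This same factor is the package's "modified Hertz"
  correction, so that solution is exact in the depth dimension and
  biased only by finite sample size, mirroring its reported behaviour.
* `c_thick = 1 + 1.133 χ_H + 1.283 χ_H² + 0.769 χ_H³ + 0.0975 χ_H⁴`,
  with `χ_H = √(Rδ)/H` — the established bonded-sample finite-thickness
  correction: thin samples on a rigid base push back harder.
* `c_width = 1 − 0.6 exp(−0.2 W/√(Rδ))` — edge-compliance softening of
  narrow samples, calibrated once so the narrowest design corner
  (`W = 5R` at full depth) is ~15% softer.
* `g = 1 + k x²/J_m` with `k = 1` — Gent strain stiffening. `k x²` plays
  the role of the invariant excess driven by contact strain (0.25 at
  full depth); the form is the leading-order expansion of the Gent
  amplification and is nonsingular over the whole admissible `J_m`
  range, unbounded as `J_m → 0` (lock-up), and `→ 1` as `J_m → ∞`.

All coefficients live in one configuration block (`SurrogateCoeffs`).
Forces are exactly linear in `μ` at fixed `K/μ`, as for any hyperelastic
solid. Curves are smooth, monotone, power-law-like, and respond to
geometry with the expected trends (deeper ⇒ stiffer, thinner ⇒ stiffer,
narrower ⇒ softer).

**What the surrogate is not.** It is a stand-in with the right structure
and trends, not a converged FE solution: it has no contact-pressure
distribution, no friction/adhesion/surface tension, no viscoelasticity,
and its correction factors are separable where the true physics is not.
Consequently, passing the bundled validation demonstrates that the
pipeline learns and inverts its generator accurately — the
generator-agnostic claim — not that the shipped networks are accurate
for laboratory data. Users with the FEBio solver can regenerate the
ground truth externally: `write_febio_deck` emits version-3.0 XML decks
(hex block, rigid sphere, frictionless sliding contact, fixed bottom
face, one load step per depth increment) and `read_harvest` ingests the
resulting (depth, force) tables; the rest of the pipeline is unchanged.
The bottom face is taken as bonded (the common mounted-sample
condition); lateral faces are free.

## Design space and sampling

Non-dimensionalised by `R`: `W/R, H/R ∈ [5, 40]` (linear),
`μ ∈ [10², 10⁶] Pa` (log₁₀), `J_m ∈ [5·10⁻⁴, 5]` (log₁₀ by default,
configurable to linear). Latin-hypercube sampling stratifies each
dimension into `n` equal-probability bins with exactly one sample each,
after the scale transform. Depth is not a sampled coordinate: every
design point is evaluated on the shared grid `δ/R = 0, 0.005, …, 0.5`
(101 points; the identically zero force at zero depth is stored but
excluded from learning targets, leaving 100). Default splits are 10 000
training, 1250 validation, 1250 test curves per model — 25 000 curves in
total — with distinct split seeds.

## Networks

Both networks are fully connected with leaky-ReLU hidden activations
(slope 0.3) and linear outputs, trained with minibatch Adam (batch 64)
under a cosine learning-rate decay, retaining the best-validation-epoch
weights. The trainer is a compact dense-net module inside the package
(Glorot initialisation, MSE/MAE losses, deterministic for a given seed).

**Forward surrogate** — inputs `(W/R, H/R, log₁₀μ[, log₁₀J_m])`, min–max
scaled to [0, 1] against the design bounds; outputs the 100-point curve;
hidden widths (4, 4, 100, 100, 100); MSE loss. Targets are the per-depth
z-scores of `log₁₀(F/(μR²))`: scaling out `μ` (exact linearity) and
taking logs makes the learning signal uniform in relative terms across
four decades of stiffness and the strong Gent force range. Validation
error is reported as the curve-level relative ℓ₂ error on physical
forces.

**Direct inverse** — curves are first summarised by the two-parameter
power law `F = p δ^s` (ordinary least squares on
`ln F = ln p + s ln δ`, fitted on `δ/R` with `F/R²`, excluding
non-positive points; a closed-form, deterministic step that also acts as
a low-pass filter). Inputs `(W/R, H/R, log₁₀p, s)`, min–max scaled on
the training split; hidden widths (4, 4, 4, 4, 2); output `log₁₀μ`
(plus `log₁₀J_m` for Gent); MAE loss. Internally the network learns
`log₁₀μ − log₁₀p` — the modulus is a known multiple of the power-law
prefactor up to geometry/stiffening corrections, and learning only that
correction is far easier for the deliberately narrow architecture
(absolute targets plateau at several percent error; the
reparameterisation reaches sub-percent). Predictions are always returned
as absolute `log₁₀` parameters. For the Gent model, four random restarts
are trained and the one with the lowest validation-split modulus error
retained: the narrow architecture is initialisation-sensitive, restarts
trade modulus against stiffening-parameter accuracy, and the modulus is
the primary reported parameter. Selection on the validation split is
standard network selection.

Training schedules (epochs) differ per task because the tasks differ:
neo-Hookean forward 200, Gent forward 600 (the stiffening response is a
genuinely harder function), neo-Hookean inverse 1500, Gent inverse
4000 × 4 restarts. These were set by convergence studies on the
training/validation splits only.

## Inversion

**Least squares through the forward net** — bound-constrained trust
region (`scipy.optimize.least_squares`, TRF) over `log₁₀μ` (and
`log₁₀J_m`) within the design bounds, multi-started from a 5-point latin
hypercube of the bounds; ties break toward the lowest misfit, then the
lowest `μ`. Measured curves are linearly interpolated onto the standard
depth grid; depths beyond the measured range are excluded (no
extrapolation). Residuals are **per-point relative force residuals**
(`(F̂ᵢ − Fᵢ)/Fᵢ`; configurable to plain absolute-force residuals). This
weighting matters: strongly stiffening Gent curves have shallow-depth
forces three orders of magnitude below their peak, and it is precisely
that shallow region which separates `μ` from `J_m`. With absolute
residuals the misfit cannot see it, `μ` and `J_m` become degenerate, and
the modulus error saturates at several percent regardless of network
quality; relative residuals restore identifiability, and are also the
homoscedastic choice under multiplicative measurement noise. The
reported misfit RMSE is always in force units.

**Direct** — one power-law fit plus one network evaluation; no
iterations.

**Hertz baselines** — both contact laws are linear in `μ`, so the
least-squares modulus is the closed form `μ̂ = ΣFᵢgᵢ/Σgᵢ²` with `g` the
unit-modulus model force (optionally restricted to `δ/R ≤ 0.1` to mimic
small-strain usage). Young's modulus is reported as `E = 3μ`
(incompressible).

**Verification loop** — identified parameters can be fed back through
the generator and the RMSE against the measured curve reported.

## Evaluation metrics

Mean and maximum relative parameter errors are computed on the linear
scale, `⟨|θ̂ − θ|/θ⟩`. The coefficient of determination `R²` of predicted
versus generating parameters is computed on the `log₁₀` scale, since
both parameters are sampled log-uniformly over ~4 decades and linear-scale
`R²` would be dominated by the top decade. Identical metrics are applied
to ML routes and Hertz baselines.

Two robust qualitative findings under the default conditions: the
stiffening parameter is identified less accurately than the modulus, and
its error grows with `J_m` — the Gent factor's influence on the curve
scales as `1/J_m`, so the information content vanishes at the top of the
range. Conversely the smallest `J_m` values are the easiest, because
stiffening dominates the curve there.

## Noise robustness

Neither network is trained on noise. The least-squares route is
protected because the forward network can only produce smooth curves;
the direct route is protected by the power-law step, which compresses a
noisy 100-point curve into two fitted parameters. The bundled checks add
2% multiplicative Gaussian force noise to held-out curves and verify
that both routes degrade by less than a factor of five, and that a
direct network fed raw (log-)force values instead of power-law features
degrades far more under identical noise.

## Experimental curve ingestion

Two-column text files (displacement, force) with `# key: value` metadata
for `R`, `W/R`, `H/R` and units; micrometre/micronewton declarations are
converted to SI. Depths are sorted, duplicates dropped, and an optional
pre-contact baseline (forces below a configurable fraction of the peak)
is trimmed with the depth axis re-zeroed at contact; by default the file
is assumed to start at contact. Small negative force readings are
clipped to zero.

## Numerical choices and degenerate inputs

* Depth grid step must divide the range to 10⁻¹²; the grid is inclusive
  of both ends.
* Power-law fits require ≥ 3 positive points; a warning is logged if
  more than 20% of points are excluded.
* All-zero curves make the closed-form Hertz fit raise, and make the LS
  route return a flagged, non-converged result at the lower modulus
  bound.
* Gent evaluation raises a lock-up error at `Ĩ₁ − 3 ≥ J_m`; the energy
  uses `log1p` for precision in the neo-Hookean limit.
* LS tolerances: `xtol = ftol = 10⁻¹⁰`, `gtol = 10⁻¹²`, finite-difference
  step 10⁻⁵ in the log-parameters.
* Optimiser bound hits are reported via an `at_bound` flag; parameters
  are clipped to the design bounds.
* Dataset archives and model archives are deterministic (fixed zip
  timestamps): identical seeds produce byte-identical files.

## Problem sizes used by the bundled validation

The acceptance script and the full-scale test fixture run both models at
the complete study scale — 10 000/1250/1250 curves per model — with the
training schedules above; the whole pipeline takes on the order of ten
minutes on one CPU core. Unit and property tests run reduced smoke
configurations (hundreds of curves, short schedules) of the same code
paths.

## Known limitations

* The surrogate's separable correction structure understates the
  interaction of depth, thickness and width effects present in a true
  FE solution; magnitudes tied to FE ground truth (e.g. absolute Hertz
  baseline errors) are condition-dependent here.
* Friction, adhesion, surface tension, viscoelasticity and contact-point
  uncertainty are out of scope; real instrument data violate these
  assumptions to varying degrees.
* The depth-correction, width-softening and Gent-stiffening coefficients
  are package calibrations, not measured constants; all are overridable
  in configuration.
* `R²` on the log scale and relative errors on the linear scale is a
  reporting convention; comparisons against numbers computed under other
  conventions should account for it.
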