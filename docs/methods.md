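# Methods

This note documents the models, the numerical choices, and what the
synthetic study does and does not emulate.

## Spectral model

The loss at one (T, P) state point is modelled as

ε″(f) = σ_dc/(ε₀2πf) − Im Σ_k Δε_k · L_k(2πf τ_k)

with L = (1 + iω τ)^−d (Cole-Davidson) for the slowest (α) process and
L = [1 + (iωτ)^c]^−1 (Cole-Cole) for the secondaries. Complex powers use
the principal branch; because Re(1 + iωτ) > 0, the loss of every valid
component is non-negative. Both families reduce bit-for-bit to the Debye
function at shape exponent 1. The dc term is added to the imaginary part
only, so predicted ε′ excludes it. ε₀ = 8.854·10⁻¹² F/m and
R = 8.314 J mol⁻¹ K⁻¹ live in `glassdyn.models` as the single source of
truth. Units package-wide: T in K, P in MPa, f in Hz, τ in s, specific
volume in cm³/g, molar volumes in cm³/mol (MPa·cm³ = J makes all
exponents dimensionless).

## Spectral fitting

The objective is unweighted least squares on log₁₀ ε″ over the points with
ε″ ≥ 10⁻³ (an instrument-noise floor). The log objective keeps the
decade-spanning dc upturn from dominating the α peak. ε′ is not fitted;
when present it only seeds ε∞, which does not enter the loss and is
therefore carried, not varied.

Seeding: σ_dc is bounded above by min over the first two decades of
ε₀·2πf·ε″ (every loss term is positive, and near-equality holds in the
slope −1 region); peak detection runs on the residual after subtracting
that bound, smoothed by a short Savitzky-Golay filter, with ≥ 1 decade
peak separation, and excluding the region where the dc term still
dominates the residual (there the subtraction leaves amplified noise,
not signal). Processes hidden as shoulders leave no maximum; missing
seeds go into the largest log-frequency gaps. Δε seeds are 2× peak
height, shapes start at 0.8.

Fitting proceeds by a staged release (dc+α on the low-frequency window,
then +β, then +γ, then joint refinement); because bad seed assignment
can trap the staged path, a direct joint fit from the raw guess is run
as a cheap restart and the lower-residual solution kept. Relaxation
times are bounded to the measured window ±2 decades, strengths to
Δε ≤ 100. On noiseless in-model-class spectra the decomposition recovers
parameters to ~10⁻¹⁴ relative; at 2% multiplicative noise τ errors are
at the percent level for well-separated processes.

Two processes closer than ~1.5 decades with a 10:1 strength ratio are
*not* separately identifiable — the compound peak is numerically
indistinguishable from a single slightly broadened one. The pipeline
therefore chooses the per-spectrum process count (1–3) by BIC, discards
fitted components whose loss maximum falls outside the measured window
or whose strength pins at a bound, and applies a 3×median residual
quality cut before assembling the relaxation map. Map rows are labelled
α/β/γ by descending τ after that filtering.

## Relaxation-map analysis

* VFT fits run on log₁₀ τ with multi-start over T_VF and a soft-L1 loss
  (scale 0.1 decades) so an occasional mis-deconvolved spectrum cannot
  bend the curve; only equilibrium points (τ_α ≤ 100 s) enter. T_VF must
  fall below the data range or the fit errors out.
* Tg, Pg and fragility are reported from closed forms
  (Tg = T_VF(1 + s/ln(τ_g/τ∞)), Pg = (RT/V_a)ln(τ_g/τ₀),
  m = s·T_VF·Tg/[ln10(Tg−T_VF)²]), which the tests verify against
  numerical root-finding/differentiation to 10⁻⁶ relative. τ_g = 100 s
  is the package-wide glass-transition convention.
* The Andersson-Andersson fit works in GPa to condition k₂ and retries
  from a small k₂ seed grid.
* The β-process kink is a continuous two-segment line in (1/T, ln τ)
  with the break scanned over all admissible positions (≥ 4 points per
  side), accepted only if an F-test against the single line passes at
  α = 0.05; ties within 1% RSS resolve toward an independently supplied
  Tg; the break uncertainty comes from a seeded 200-resample residual
  bootstrap. Glass-side slope is reported as `slope_below`.

## Equation of state and scaling

The Tait reference temperature T₀ is a fixed convention (default 300 K):
shifting T₀ only rescales v₀, so the two cannot be fitted jointly. b₃
requires at least two isotherms; a single isotherm raises an explicit
error. Fits use bounded least squares from a single physical start.

The master-curve γ minimises the pooled RSS of one monotone cubic
regression spline in x = 1000/(T·v^γ) (I-spline construction: intercept
plus non-negative coefficients on integrated B-splines over 6 equally
spaced knots, solved by bounded linear least squares). Monotonicity is
the only shape assumption — the master curve is visibly curved and no
parametric form is imposed. The search is a 0.1-step grid on [0.5, 8]
refined to 0.01 by bounded minimisation; the quoted uncertainty is the
half-width of the profile region with RSS ≤ 1.05×min (a curvature-based
SE is also stored). Only supercooled-liquid α points enter the headline
γ. β-process collapse is assessed at the α-optimal γ with its own
spline; the same fixed-γ dispersion is used to show that the
density-insensitive γ process does not collapse. A single thermodynamic
path cannot identify γ and raises an error.

The isochronal estimator inverts each isobar's VFT fit at
τ ∈ {10⁻⁶, 10⁻⁴, 10⁻², 10⁰, 10²} s, maps (P, T_τ) to v through the EOS,
and takes γ = −slope of ln T vs ln v across isobars, reporting the mean
± sd over isochrones. The static-quantity relation
γ = [ΔC_P·κ_T/(Δα_P·V_g) − α_P·Tg]⁻¹ is evaluated exactly, with
first-order error propagation when input uncertainties are supplied; a
non-positive denominator is reported as an error, never masked.

## Superposition diagnostics

Isochronal lineshapes are dc-subtracted using the *fitted* σ_dc (a
low-frequency extrapolation would double-count β intensity), normalized
to the α peak located on the model curve, and compared as log-loss vs
log-frequency on a 0.05-decade grid with horizontal shifts limited to
±0.2 decades. The comparison window is ±3 decades around the α peak:
the intramolecular γ process is temperature-activated and therefore not
isochronal-invariant, so its spectral region carries no information
about α-shape superposition. Points where the dc background exceeds
twice the remaining signal are excluded — after subtraction they contain
amplified noise. With the 2% noise model the matched-τ_α distance floor
is √2·0.02/ln10 ≈ 0.012 decades.

## The synthetic study

The generator emulates a combined dielectric + PVT campaign: isobars at
ambient pressure, 0.2, 0.4 and 0.6 GPa sampled every 2 K from Tg−28 K to
Tg+32 K, and isotherms at 260–320 K sampled at 15 pressures up to just
beyond Pg; PVT tables at 303–368 K up to 0.3 GPa with 0.1% volume noise.
Frequency windows are 10⁻²–10⁹ Hz at ambient and 10⁻²–10⁷ Hz under
pressure, 8 points per decade.

Ground truth: the α process is *exactly* scaling-consistent — at every
state Log τ_α = F(1000/(T·v^γ)) with γ = 2.0, where F is the ambient
VFT law (τ∞ = 10⁻¹⁴ s, s = 10.62, T_VF = 180 K, hence Tg = 231.9 K,
m = 71.5) transported through the Tait EOS (v₀ = 0.80 cm³/g,
α_v = 7·10⁻⁴ K⁻¹, T₀ = 300 K, k = 0.0894, b₁ = 800 MPa,
b₃ = 4.5·10⁻³ K⁻¹ — plausible values for an organic melt of this
density; the material's own EOS coefficients are not published, so the
fixture carries its own). Outside the ambient-anchored range F continues
linearly in x (only deep-glass extrapolation states land there). β_KWW
falls linearly in Log τ_α from 0.95 to 0.60 at 100 s; τ_β follows the
Coupling Model (t_c = 2 ps) in the liquid and a reduced-slope (ratio
0.55) Arrhenius line below Tg(P), creating the kink. The γ process is
Arrhenius (τ₀ = 3·10⁻¹⁸ s, E_a = 42 kJ/mol) with V_a = 1.5 cm³/mol —
under 0.2 decades of pressure dependence across 0.6 GPa. Strengths:
Δε_α = 2500/T, β at 10% and γ at 5% of the α strength (Δε schedules are
plausible placeholders, not published values); σ_dc = 10⁻¹² S/m·s / τ_α.
Noise: 2% multiplicative log-normal on ε″ and 0.02 decades on map times,
all drawn from one generator seeded in the configuration; the same seed
reproduces the dataset bit-for-bit, and a different seed changes only
the noise.

What the generator does **not** emulate: electrode polarization, cell
parasitics, high-frequency reflectometry artifacts, temperature-dependent
ε∞, conductivity exponents ≠ 1, or any glass-state EOS deviation (the
Tait surface is extrapolated below Tg exactly as the analysis would).
Passing tests therefore demonstrate correctness of the estimators under
a clean, scaling-consistent world with realistic noise — not robustness
to every instrumental artifact of real spectra.

## Problem sizes and known limitations

The default study holds ~180 state points, ~100 of which have the α peak
inside the measurable window and become spectra; a full
spectra-to-summary pipeline run fits them in well under a minute, and
the statistical tests use 20 seeded noise realizations per recovery
check. The α/β merging ambiguity above is intrinsic, not numerical: in
that regime the reported τ_α of *any* deconvolution carries ~0.1–0.2
decade systematic uncertainty, which is why the γ estimators and VFT
fits are built to be robust to it. The fragility decrease with pressure
encoded in the fixture (~6 units between ambient and 0.6 GPa) is
comparable per-isobar-step to the scatter that 2% τ noise induces in m,
so neighbouring-isobar ordering is only guaranteed on noise-free data.
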