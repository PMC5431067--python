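# glassdyn

Pressure- and temperature-dependent dipolar dynamics of molecular glass
formers, built around the amorphous drug ternidazole
(3-(2-methyl-5-nitroimidazol-1-yl)-propan-1-ol, TDZ) as the model system.

Broadband dielectric spectroscopy of a supercooled liquid measures the
loss ε″(f) over many decades of frequency at each (T, P) state point.
`glassdyn` turns such spectra — together with PVT (specific volume)
data — into the standard quantitative description of the material's
molecular mobility, and tests whether the dynamics obeys *thermodynamic
(density) scaling*: the collapse of all relaxation times onto one master
curve in the single variable T·v^γ.

## What it computes

**Spectral decomposition.** Each loss spectrum is fitted as a sum of a dc
conductivity term σ_dc/(ε₀2πf), a Cole-Davidson α relaxation
ε(f) = ε∞ + Δε/(1 + i2πfτ_α)^d, and Cole-Cole secondary processes
ε(f) = ε∞ + Δε/[1 + (i2πfτ)^c] (the Johari-Goldstein β and an
intramolecular γ process). The Kohlrausch stretching exponent follows from
β_KWW = d^(1/1.23).

**Relaxation-map analysis.**

* Vogel-Fulcher-Tammann law τ_α(T) = τ∞ exp[s·T_VF/(T − T_VF)] per isobar;
  Tg defined by τ_α(Tg) = 100 s; fragility
  m = s·T_VF·Tg/[ln10·(Tg − T_VF)²].
* Pressure-Arrhenius law τ_α(P) = τ₀ exp(P·V_a/RT) per isotherm, giving
  the activation volume V_a and the glass-transition pressure Pg.
* The sublinear Andersson-Andersson law Tg(P) = k₁(1 + k₂P)^k₃.
* A two-segment Arrhenius fit (F-tested, bootstrapped) that locates the
  slope kink of the β process at the glass transition.
* Coupling-Model consistency τ_CM = t_c^(1−β_KWW)·τ_α^(β_KWW), t_c = 2 ps.

**Equation of state.** The Tait form
v(P,T) = v₀[1 + α_v(T−T₀)][1 − k ln(1 + P/(b₁e^(−b₃T)))].

**Scaling exponent γ by three independent methods:**

1. *master curve* — minimize the pooled residual of a single monotone
   spline in x = 1000/(T·v^γ) over candidate γ;
2. *isochronal slope* — γ = −d ln T/d ln v along lines of constant τ_α;
3. *static thermodynamics* — γ = [ΔC_P·κ_T/(Δα_P·V_g) − α_P·Tg]⁻¹.

**Superposition diagnostics.** Isochronal lineshape comparison (spectra
with equal τ_α at different (T, P)) and the generalized Angell plot
(log τ vs Tg(P)/T).

A seeded synthetic-data module generates complete TDZ-like studies
(spectra, PVT tables, relaxation maps) with known ground truth, so every
stage of the pipeline is testable without any measured data.

## Worked example

```python
import glassdyn as gd

# 1. synthetic study with known ground truth (gamma = 2.0)
truth = gd.default_tdz_config(seed=42)
ds = gd.generate_dataset(truth, include_spectra=False)

# 2. equation of state from the PVT table
tait = gd.fit_tait(ds.pvt)

# 3. ambient-pressure VFT analysis
alpha = ds.relaxation_map.query("process == 'alpha' and tau_s <= 100")
amb = alpha[alpha.P_MPa == 0.1]
vft = gd.fit_vft(amb.T_K, amb.tau_s)
Tg = gd.glass_transition_temperature(vft)
print(f"Tg(ambient)  = {Tg:6.1f} K")
print(f"fragility m  = {gd.fragility(vft, Tg):6.1f}")

# 4. thermodynamic scaling exponent, three ways
mc = gd.gamma_master_curve(ds.relaxation_map, tait)
fits = [(P, gd.fit_vft(g.T_K, g.tau_s))
        for P, g in alpha.groupby("P_MPa") if g.T_K.nunique() >= 5]
iso = gd.gamma_isochronal_slope(fits, tait)
td = gd.gamma_thermodynamic(gd.default_thermo_quantities())
print(f"gamma (master curve)     = {mc.gamma:.2f} +/- {mc.se:.2f}")
print(f"gamma (isochronal slope) = {iso.gamma:.2f} +/- {iso.se:.2f}")
print(f"gamma (static quantities)= {td.gamma:.2f}")
```

prints

```
Tg(ambient)  =  231.9 K
fragility m  =   71.4
gamma (master curve)     = 2.01 +/- 0.05
gamma (isochronal slope) = 2.00 +/- 0.03
gamma (static quantities)= 2.00
```

The glass transition sits at 231.9 K, the material is a fragile glass
former (m ≈ 71), and the three mutually independent estimates of the
scaling exponent agree at γ ≈ 2 — the signature of isomorph-like density
scaling, recovered here from data whose generator encoded γ = 2 exactly.

A command-line interface mirrors the stages
(`glassdyn simulate | fit-spectra | relax-fit | eos-fit | scale |
superpose | run-all`); `glassdyn run-all --simulate` runs the whole chain
from spectra to the scaling report and writes a `summary.json`.

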