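# sfex — supercritical-CO₂ extraction modelling toolkit

`sfex` models the recovery of essential oil from milled *Pistacia
lentiscus* (mastic) leaves by supercritical CO₂ extraction, and the
economics of scaling that process up. It is aimed at process engineers
and natural-product researchers who have packed-bed extraction curves
(cumulative extract mass vs. time) and want kinetic parameters,
mass-transfer correlations, designed-experiment yield models and
cost-of-manufacturing estimates from one consistent code base.

## What it computes

**Extraction kinetics — broken-and-intact-cell (BIC) model.** Milling
breaks a fraction *G* of the plant cells; their oil leaves through the
fluid film while intact-cell oil must diffuse through the solid. With
dimensionless time ψ = t·Q·y_s/(N·x₀) and transfer groups

    Z = N·k_f a₀·ρ_f / (Q(1−ε)ρ_s),   Y = N·k_s a₀·x₀ / (Q(1−ε)y_s),

the extracted fraction e = E/(N·x₀) follows the classical three-period
analytical solution: a film-limited linear period (ψ < G/Z), a
transition period while the broken/intact boundary h_k crosses the bed
(G/Z ≤ ψ < ψ_k), and a diffusion-limited tail. `sfex.fitting` estimates
(G, k_s a₀, k_f a₀) from a sampled curve by bounded multistart least
squares, either fitting all three parameters or pinning k_f a₀ from a
film correlation.

**Film mass transfer.** `sfex.transport` provides Re, Sc, Sh, the
power-law correlation Sh = c₀·Re^c₁·Sc^{1/3} (c₁ ∈ [0.5, 0.8]) and its
calibration from observed Sherwood numbers, plus a dense-gas estimate of
the α-pinene/CO₂ binary diffusivity.

**Yield response surface.** `sfex.rsm` fits the two-level,
three-factor interaction model
Y_D = a₀ + a₁x₁ + a₂x₂ + a₃x₃ + a₁₂x₁x₂ + a₁₃x₁x₃ + a₂₃x₂x₃
(x₁ = pressure, x₂ = particle size, x₃ = CO₂ flow, coded to [−1, 1]) by
OLS, with t-based inference, leave-one-out predicted R², between-term
correlation diagnostics and D-optimal subset selection by Fedorov
exchange.

**Scale-up economics.** `sfex.economics` evaluates the annualised cost
of manufacturing COM = 0.340·FCI + 2.73·C_OL + 1.23·(C_UT + C_WT +
C_RM) for two-vessel plants of 0.1–1.0 m³, with the solvent flow scaled
from the laboratory bed by Q₂/Q₁ = (F₂/F₁)²·(H_B1/H_B2)·(d_B1/d_B2).

**Synthetic data.** The study's raw kinetic weighings were never
published, so `sfex.synth` generates stand-in curves (forward model +
Gaussian weighing noise, 30-min sampling over 8 h) and synthetic design
responses; the printed design, parameter and cost tables ship as
packaged CSV fixtures (`sfex.datasets`).

## Worked example

```python
import sfex
from sfex import datasets, rsm, synth, fitting

# yield model on the packaged ten-run design
design = rsm.DesignTable(
    coded=datasets.load_coded_design()[["x1", "x2", "x3"]],
    yields=datasets.load_yields()["yield_pct"].to_numpy())
fit = rsm.fit_rsm(design)
print(f"a0={fit.coefficients['a0']:.3f}  a1={fit.coefficients['a1']:.3f}"
      f"  t(a1)={fit.tvalues['a1']:.2f}  R2={100*fit.r2:.1f}%")
print("kept at alpha=0.05:", list(rsm.reduce_model(fit, 0.05).index))

# kinetic refit of a synthetic curve for the highest-yield run
system, truth = synth.experiment_system(2)
curve = synth.gen_curve(synth.CurveGenSpec(system=system, params=truth,
                                           noise_sigma=0.0))
res = fitting.fit_bic(curve)
print(f"G={res.params.G:.3f}  ksa0={res.params.ksa0:.2e} 1/s  "
      f"kfa0={res.params.kfa0:.2e} 1/s  R2={res.r2:.4f}")
```

prints

```
a0=0.183  a1=0.084  t(a1)=3.71  R2=91.2%
kept at alpha=0.05: ['a0', 'a1']
G=0.610  ksa0=7.01e-05 1/s  kfa0=1.72e-03 1/s  R2=1.0000
```

The yield model explains 91.2% of the run-to-run variation and retains
only the intercept and the pressure effect at the 5% level: raising the
CO₂ pressure from 80 to 220 bar adds 2×0.084 ≈ 0.17 percentage points
of yield, while particle size and flow are not resolved by this design.
The kinetic refit recovers the generating parameters of the synthetic
curve exactly: G = 0.61 of the cells are broken by milling, and
internal diffusion (k_s a₀ ≈ 7×10⁻⁵ s⁻¹) is ~25× slower than film
transfer (k_f a₀ ≈ 1.7×10⁻³ s⁻¹).

The same stages are scriptable from the shell (`sfex simulate`, `sfex
fit`, `sfex transport dab|fit-sh`, `sfex rsm fit|doptimal`, `sfex econ
com`, `sfex synth curve|doe`, `sfex pipeline`); `sfex pipeline --outdir
out` runs synthetic curves → kinetic fits → Sherwood calibration →
yield model → cost matrix and writes `fit_exp*.json`, `sherwood.json`,
`rsm.json`, `com.csv` and a human-readable summary.

## Layout

    src/sfex/        bic, transport, fitting, rsm, economics, synth,
                     datasets, io, config, pipeline, cli, constants
    src/sfex/data/   packaged study tables (CSV)
    tests/           pytest suite (unit, property and acceptance tests)
    docs/methods.md  model assumptions, defaults and limitations
    scripts/         acceptance.py
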