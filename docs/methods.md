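# Methods

## Extraction kinetics

The package implements the analytical broken-and-intact-cell (BIC)
solution for isothermal, isobaric packed-bed supercritical extraction
with a type-A (solubility-bounded) equilibrium. Assumptions: plug flow
of solvent through a homogeneous bed; solute in broken cells limited by
the fluid film; solute in intact cells limited by solid-phase
diffusion; negligible axial dispersion and bed shrinkage; constant
solvent properties over a run. The cumulative curve is the three-period
piecewise solution in dimensionless time ψ = t·Q·y_s/(N·x₀):

- period 1 (ψ < G/Z): e = ψ(1 − e^{−Z});
- period 2 (G/Z ≤ ψ < ψ_k): e = ψ − (G/Z)·e^{Z(h_k−1)} with
  h_k = (1/Y)·ln[1 + (e^{Y(ψ−G/Z)} − 1)/G];
- period 3 (ψ ≥ ψ_k): e = 1 − (1/Y)·ln{1 + (e^Y − 1)·e^{Y(G/Z−ψ)}(1−G)}
  with ψ_k = G/Z + (1/Y)·ln[1 + G(e^Y − 1)].

Two readings in the printed formulas are fixed by continuity: the
symbol pair "GZ" is the quotient G/Z (only then do periods 1 and 2
agree at the boundary), and the trailing G in the h_k expression is a
divisor (only then does substituting ψ_k give h_k = 1; substituting the
ψ_k expression into period 2 then reproduces period 3 at the boundary
exactly, which the property tests assert to < 1e-10 over 1000 random
parameter draws). Numerically: boundary points are assigned to the
later period, Y(ψ − G/Z) exponents are clipped at 700 before
exponentiation, and `log1p`/`expm1` are used throughout, so the curve
is finite for any admissible (G, Z, Y).

### Parameters and defaults

| quantity | meaning | default | why |
|---|---|---|---|
| N | feed mass | 0.023 kg | laboratory charge |
| ε | bed void fraction | 0.53 | measured bed |
| ρ_bulk | bed apparent density | 291 kg/m³ | measured bed |
| ρ_s | solid true density | 1400 kg/m³ | see below |
| T | temperature | 313.15 K | all runs at 40 °C |
| y_s | oil solubility in CO₂ | 1e-4 kg/kg (placeholder) | unpublished; see below |
| x₀ | extractable-oil fraction | asymptote/N | see below |

ρ_s: the bed relation ρ_bulk/(1−ε) would give 619 kg/m³, which is
*below* the CO₂ density at 220 bar (857 kg/m³); a settled bed of such a
solid could not exist in that solvent, so the printed ρ_bulk and ε
cannot describe the same packing state. The default is a typical
lignocellulosic true density of 1400 kg/m³, overridable in config.

y_s and x₀ are not measurable from a single extraction curve: ψ only
rescales time by y_s, so (y_s, Y) co-vary and any positive y_s yields
an equivalent re-parameterised fit. The package therefore treats y_s as
a required, documented input (a placeholder by default) rather than
inventing a literature solubility, and takes x₀ = (asymptotic extract
mass)/N, which makes e → 1 by construction.

## Parameter estimation

`fit_bic` minimises the RMSE between observed and modelled cumulative
masses over (G, log₁₀ k_s a₀, log₁₀ k_f a₀). Residuals are evaluated in
fraction space internally — the argmin is identical (the two losses
differ by the constant N·x₀) but the problem is O(1)-conditioned for
the solver's absolute tolerances. Because the period boundaries move
with the parameters the loss surface is only piecewise-smooth, so the
bounded trust-region solver is started from 8 Latin-hypercube points
over G ∈ [0.05, 0.95], k_s a₀ ∈ [1e-7, 1e-2] s⁻¹ and k_f a₀ ∈ [1e-5, 1]
s⁻¹ (log-spaced), seed 20200103; ties are broken by lowest RMSE, then
lowest G. Convergence: xtol 1e-10, ftol 1e-12, ≤ 2000 evaluations per
start. The `correlation_kf` route holds k_f a₀ fixed (from the film
correlation via D_AB → Sc, bed geometry → Re, Sh → k_f, spheres rule →
a₀) and frees only (G, k_s a₀).

Identifiability: a curve sampled only in the film-limited period is
linear and leaves (G, k_s a₀) unresolved; one sampled only in the
diffusion-limited tail leaves k_f a₀ unresolved. The fitter detects
both situations (near-perfect linearity of the observed curve, or all
samples beyond the fitted ψ_k) and emits an `IdentifiabilityWarning`
instead of failing.

## Film transfer and diffusivity

Sh = c₀·Re^c₁·Sc^{1/3} with c₁ constrained to [0.5, 0.8]; calibration
is least squares of log(Sh/Sc^{1/3}) on log Re (a power law is linear
in logs), with the slope clipped to the physical window and the
prefactor re-estimated if clipping engages. The stated validity window
2 ≤ Re ≤ 60, 2 ≤ Sc ≤ 12 is flagged by warning, never enforced — the
laboratory runs themselves sit below it (Re ≈ 0.1–0.7).

The α-pinene/CO₂ diffusivity uses a dense-gas correlation built from
the solvent's near-critical self-diffusivity, D₁₂ = 5.152·D_c·T_r·
(ρ_r^{−2/3} − 0.4510)/X, with X a critical-volume/mass ratio of the
pair and documented CO₂ and α-pinene constants. The reduced-density
term carries the entire pressure dependence and reproduces the
tabulated high/low-density diffusivity ratio to 1%; the absolute level
depends on constants the study does not disclose and is treated as an
order-of-magnitude estimate (asserted within a factor of 10). The
characteristic length in all Sh↔k_f conversions is the particle
diameter. The specific interfacial area follows the spheres rule, a₀ =
6(1−ε)/d_p on a bed-volume basis by default, with the particle-volume
basis 6/d_p selectable — the published tables only ever report the
lumped products k_s a₀ and k_f a₀, and their printed (k_f a₀, Sh, D_AB)
triples back-solve to an a₀ two orders of magnitude below either
convention, so no single convention can be inferred from them.

## Response-surface analysis

OLS of the yield on [1, x₁, x₂, x₃, x₁x₂, x₁x₃, x₂x₃]; factor
semantics are bound to the coded design table (x₁ pressure, x₂ particle
size, x₃ flow), and the 3-decimal observed yields are used rather than
their 2-decimal roundings. Inference is two-sided t with df = n − 7
(= 3 for the packaged design); predicted R² = 1 − PRESS/SS_tot with
hat-matrix leave-one-out residuals e_i/(1 − h_ii). On the packaged
design the predicted R² is strongly negative (−40.6): with three
residual degrees of freedom the LOO residuals of the near-saturated
model explode, so the published 0.998 cannot come from this standard
definition and the package reports what the definition gives.

The design-vetting correlation matrix is the plain Pearson correlation
of the six slope columns of the model matrix. This is the quantity that
reproduces the published matrix entry-for-entry; the alternative
(normalising the (X'X)⁻¹ covariance of the estimates) gives a different
matrix and is not what the study tabulated. It depends on the factor
settings only, never on the yields.

D-optimal subset selection maximises det(X'X) by Fedorov exchange from
a random full-rank start (seed 20200103, ≤ 1000 passes), accepting the
single best swap per pass; log det is non-decreasing by construction
and the algorithm terminates at a fixed point. For small candidate sets
the tests validate it against exhaustive enumeration.

## Scale-up economics

COM = 0.340·FCI + 2.73·C_OL + 1.23·(C_UT + C_WT + C_RM), with the
0.340·FCI term taken as already containing depreciation. Defaults: two
vessels alternating extraction/reconditioning (one bed always
extracting, 8000 one-hour batches/yr); bed density 296 kg/m³; two
workers on duty at 6.60 USD/h (a full-headcount payroll of six is a
config switch); all three solvent-cycle specific energies (|−261.29| +
219.2 + 55.0196 kJ/kg CO₂) charged at 217.10 USD/MWh; 2% CO₂ make-up at
0.15 USD/kg; leaves at 1.35 USD/kg; ethanol price carried but default
quantity zero (no cleaning quantity is stated); waste treatment zero.
FCI is exact at the tabulated vessel volumes and log-log interpolated
between them, scaled linearly by CEPCI from the 2014 reference of 580.
The vessel solvent flow comes from the kinetic-similarity rule
Q₂ = Q₁·(F₂/F₁)²·(H_B1/H_B2)·(d_B1/d_B2) anchored at the laboratory bed
(23 g, H/d = 3.6, 3.36×10⁻⁵ kg/s).

Because COM contains no yield-dependent term, the specific cost
COM/extract is exactly inversely proportional to the yield — the 5:1
ratio across the 0.3%/1.5% columns of the published cost table is
reproduced to machine precision. The absolute level is not: at 0.3%
yield the leaf feed alone contributes 1.35·1.23/0.003 ≈ 554 USD per kg
of extract, and adding the capital and labor terms already exceeds the
published 999.63 USD/kg before any utility or make-up cost, under every
labor/schedule convention the model exposes. The published matrix is
also non-monotonic in vessel volume, which no cost model affine in the
stated inputs can produce. The package therefore reproduces the
*structure* of the published table and reports the absolute costs the
stated inputs actually imply (≈ 2009 USD/kg for the 0.1 m³ / 0.3%
baseline), leaving the discrepancy visible rather than recalibrating
inputs to match.

## Synthetic data

`gen_curve` adds i.i.d. Gaussian noise (default σ = 1% of N·x₀) to the
forward model on a 30-min grid over 8 h — the simplest model consistent
with independent cumulative weighings; noisy curves are clipped at zero
but *not* re-monotonised. The packaged fixture curves use each run's
tabulated curve-fitted (G, k_s a₀, k_f a₀) as generating truth, x₀ from
the run's final yield, and a per-run y_s placed so the film-limited
period ends 2 h into the run — this keeps all three extraction periods
inside the sampled window, making the closed-loop recovery tests
well-posed (the real y_s being unpublished, any positive choice is a
re-parameterisation). What passing recovery tests show is that the
estimator inverts the model it assumes at the study's sampling design
and noise scale; they cannot show robustness to the real curves'
unknown noise, drift in the manually-controlled flow, or model error in
the BIC assumptions themselves.

`gen_doe` draws yields = X·a + N(0, σ²) on any coded design;
zero-noise responses are recovered by OLS to machine precision, and the
t-interval coverage of the pressure effect is verified by simulation.

## Known limitations

- No uncertainty quantification on kinetic parameters beyond optimizer
  diagnostics; no quadratic RSM terms; no CO₂ equation of state (Table
  densities/viscosities are bundled constants); no thermodynamic
  simulation of the solvent cycle (only its net specific energies); no
  chromatographic computation.
- The dense-gas diffusivity is order-of-magnitude only; its constants
  are documented inputs, not fitted quantities.
- Problem sizes in the tests and acceptance script are the study's own
  (10 runs, 16 samples/curve, 1000 property draws), so the whole suite
  runs in well under a minute.
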