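# Methods

## Model

One ligand species distributes at equilibrium among three media: the
aqueous phase (W), a lipid bilayer phase (Lb) and a protein with a
single, saturable binding site (P). Association with the lipid is
non-saturable and described by a partition coefficient `KP_Lb_LW`, the
ratio of local (per-phase-volume) ligand concentrations. Binding to the
protein is described either by a partition coefficient `KP_P_LX` or the
molar constant `Keq_LX = KP_P_LX · V̄_P`, where `V̄_P` is the protein
molar volume. Because the three equilibria close a thermodynamic cycle,
`KP_P_LW = KP_Lb_LW · KP_P_LLb`: only two constants are independent, and
the formalism is the same whether the ligand reaches the binding site
from the water or from the bilayer — which is why a water-soluble
protein in the presence of liposomes and an intrinsic membrane protein
are treated by the same equations. What differs between the two cases is
only which equilibria are experimentally accessible; for membrane
proteins the whole-membrane coefficient
`KP_M_LW = KP_Lb_LW·V_Lb/V_M + KP_P_LW·V_P/V_M` is measured and inverted
for `KP_P_LW`.

Assumptions: a single binding site with one ligand per site; no direct
effect of the lipid on protein conformation; no kinetics (equilibrium
only); no ionization-state modelling; no temperature dependence or
activity coefficients. Multi-site or multi-occupancy binding pockets are
out of scope — those require numerical solvers and an
occupancy-dependent relation between partition coefficient and binding
constant.

## Solvers

All bulk concentrations are moles per **total** system volume. Mass
balance

```
L_T = L_W + L_Lb + L_P,    P_T = P + L_P
L_Lb = L_W · KP·V_Lb/V_W,  L_P/(P·c_W) = Keq_LW
```

closes to a quadratic `a·L_W² + b·L_W + c = 0` with

```
a = γ·keq,  b = γ − keq·(L_T − P_T),  c = −L_T,   γ = 1 + KP·α_Lb/α_W
```

The physically meaningful root is always the larger one (`x₊`); since
`c ≤ 0` the discriminant is `≥ b²`, and the root is evaluated in the
cancellation-free form `−2c/(b + √(b²−4ac))` when `b > 0`.

* **Dilute solver** (`solve_dilute`): `keq = Keq_LW` multiplies the
  per-total-volume free concentration directly. Valid when water
  dominates the system; a `DiluteRegimeWarning` (not an error) is
  emitted when `α_W < 0.99`, the stated validity bound.
* **General solver** (`solve_general`): exact volume bookkeeping. The
  local aqueous concentration `c_W = L_W/α_W` drives both the lipid
  partition and the binding step, which amounts to `keq = Keq_LW/α_W`
  in the same quadratic. It reduces to the dilute solver as `α_W → 1`
  and is cross-validated against it (≤0.1% at `α_Lb + α_P ≤ 0.01`) and
  against an independent bisection oracle on the scalar mass-balance
  residual (1e-8 relative over 1000 log-uniform parameter draws).

Degenerate inputs bypass the quadratic: `P_T = 0` or `Keq = 0` reduce to
linear partitioning `L_W = L_T/γ`; `L_T = 0` returns zeros. Tiny
negative `L_P` from roundoff is clamped to 0.

## Apparent-affinity models and bias

Two simplified analyses in common use are implemented exactly as they
are applied in practice:

* **eq6** (lipid-neglecting depletion quadratic): accounts for ligand
  bound to the protein but assigns all other ligand to the water.
* **eq7** (excess-ligand hyperbola): `L_P = P_T·K·L_T/(1+K·L_T)`,
  treating total ligand as free. The printed source of this model is
  typographically ambiguous; the standard excess-ligand hyperbola is
  adopted.

Fitting eq6 to noiseless three-compartment data recovers an apparent
constant that is *analytically* `Keq_LW/(α_W + KP·α_Lb)` — substituting
`L'_W = γ·L_W` maps the general system exactly onto the eq6 form. In the
dilute limit this is the bias relation

```
KeqApp_LW / Keq_LW = 1/(1 + KP·α_Lb)
```

independent of protein concentration. The concentrated-media form
`1/(α_W + KP·α_Lb)` follows from the same substitution and exposes the
polar-ligand exception: when `KP·α_Lb < α_Lb + α_P`, exclusion from the
lipid concentrates the ligand in the water and the apparent affinity
*exceeds* the intrinsic one (≈ +10% for KP = 0.1 at 10% v/v lipid). The
eq7 constant additionally depends on `P_T` through ligand depletion and
is biased even with no lipid at all.

`intrinsic_from_apparent` inverts the ratio; `extrapolate_to_zero_lipid`
fits `keq_app = Keq/(1 + KP·α_Lb)` across a lipid-titration series,
recovering both constants.

## Fitting choices

Single-constant fits run in `log10(Keq)` (positivity by construction,
sane step scaling across 10²–10¹⁰ 1/M) with unweighted residuals on the
observed response scale, via Levenberg–Marquardt
(`scipy.optimize.least_squares`, xtol/ftol/gtol 1e-15). Initialisation
is the half-saturation heuristic `Keq₀ = 1/L_T` at the response nearest
half its maximum, with a 5-point log-spaced multistart fallback spanning
`0.1/max(L_T)` to `10/min(L_T)`; the best residual sum wins, and the
convergence flag is reported honestly. Standard errors come from the
Gauss–Newton covariance `s²(JᵀJ)⁻¹` in log-space, mapped to the linear
scale by the delta method (`se_K = K·ln10·se_log`). The optimizer's
log-parameter is clamped to ±120 before exponentiation to keep wild
trial steps finite.

The zero-lipid extrapolation departs from a plain linear-scale
least-squares in one deliberate way: residuals are taken on
`log10(keq_app)`, because apparent affinities spanning orders of
magnitude carry multiplicative, not additive, error; the
reciprocal-linear regression (`1/keq_app` on `α_Lb`) supplies starting
values and is reported as a cross-check (it agrees exactly on clean
data, but distorts noise and is not used for inference). Series need at
least 3 points and 2 distinct lipid fractions; constant-response
titrations are rejected as degenerate rather than fitted.

## Synthetic data

`generate_titration` emulates one saturation-binding titration: a
log-spaced total-ligand grid (default 20 points spanning `0.01/Keq` to
`100/Keq`, bracketing the half-saturation point by two orders each way),
a noiseless response from the exact general solver, and additive
Gaussian noise on the saturation fraction (default σ = 0.02, a typical
relative scatter for spectroscopic or radioligand saturation data),
clipped to [0, 1]. The seed is mandatory and datasets are byte-identical
for a fixed seed. What this does **not** emulate: heteroscedastic or
instrument-specific error, drift, outliers, pipetting error on the
abscissa, or uncertainty in `KP_Lb_LW` itself — so passing recovery
tests demonstrate correctness of the estimator under the stated noise
model, not robustness to real-world artefacts. Clipping at 0 slightly
biases the lowest points upward at this σ; the effect is far below the
reported standard errors.

Scenario tables use the parameter sets given in their docstrings
(protein 50 kDa; `Keq_LW = 1e6 M⁻¹` where fixed; protein and ligand
concentrations and lipid fractions as listed). Grid densities are
configurable with a default of 50 points on the swept axis; fit-backed
tables default to 20-point titrations. Where a source axis range is not
fixed by the scenario definition (the lipophilicity axis of the
`fig6*` family, the lipid fractions of `fig2`), defaults were chosen
once to cover the physically interesting range — KP ∈ [10⁻¹, 10⁵] so the
supralinear case reaches the 10¹¹ M⁻¹ scale, and α_Lb ∈ {0, 0.1%, 1%,
5%} for the saturation-curve family. The bias columns of fit-backed
tables are computed by actually fitting the simulated curves, and are
tested against the closed-form ratio (1e-9 where the table uses the
closed form directly, 1% where a fit intervenes). In `fig5` the bias
ratio is the same for both total-ligand values, so the tables report one
fit per (KP, α_Lb) pair.

## Units and conventions

* Protein partial specific volume defaults to 0.84 mL/g (so 10 µM of a
  50 kDa protein occupies 4.2×10⁻⁴ of the system volume). Albumin-based
  compositions imply a slightly smaller value (~0.76 mL/g); the
  parameter is user-configurable and no single value is enforced.
* Equilibrium constants are stored linearly; CLI and several APIs accept
  log10 values (`--log-keq`, `--log-kp`).
* When only a CLogP is available as a lipophilicity proxy,
  `KP = 10^CLogP` is used verbatim in the worked predictions. This is a
  crude stand-in — octanol/water partitioning is a poor model of bilayer
  partitioning, and a measured `KP_Lb_LW` for the actual membrane
  composition should be preferred whenever it exists.
* Dataset CSVs are written losslessly (17 significant digits) so that
  write→read roundtrips are exact; tabular report output uses 12
  significant digits.

## Known limitations

* Single-site, single-occupancy only; no cooperativity.
* The concentrated-media solver and bias form are validated internally
  (dilute-limit reduction, oracle equivalence, fit equivalence), not
  against an external reference implementation.
* Uncertainty on corrected intrinsic constants ignores uncertainty in
  `KP_Lb_LW` and `α_Lb` beyond the first-order standard errors reported.
* The excess-ligand model's apparent constant depends on protein
  concentration; no closed-form bias expression is provided for it —
  it is characterised by simulation (`fig3`) only.
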