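# lipidbind

Ligand–protein binding affinities are almost always measured in media
that also contain lipid — detergent micelles, nanodiscs, proteoliposomes,
native membranes, or the lipoproteins of blood plasma. A ligand that
partitions into that lipid phase is *not* available to the protein, so an
analysis that counts it as free reports an **apparent** association
constant that depends on the assay composition, not an intrinsic one.
`lipidbind` implements the equilibrium framework for a single-site
protein in a three-compartment system (water **W**, lipid bilayer
**Lb**, protein **P**), for people who fit saturation-binding titrations
or need to compare affinities measured at different lipid loadings —
e.g. P-glycoprotein assays run in micelles vs native membranes.

## The model

The three pairwise equilibria form a thermodynamic cycle. With partition
coefficients defined as ratios of *local* concentrations,

```
Keq_LX   = KP_P_LX · V̄_P            (binding constant from medium X, 1/M)
KP_P_LW  = KP_Lb_LW · KP_P_LLb      (micro-reversibility)
KP_M_LW  = KP_Lb_LW·V_Lb/V_M + KP_P_LW·V_P/V_M   (whole membrane, V_M = V_Lb + V_P)
```

where `V̄_P` is the protein molar volume (default 0.84 mL/g specific
volume, i.e. 42 L/mol for 50 kDa). Mass balance over the three
compartments closes to a quadratic in the free aqueous ligand `L_W`;
the physical root is always the larger one. Two solvers are provided:
a dilute-regime solver (valid for water volume fraction `α_W ≥ 0.99`)
and an exact-volume-bookkeeping solver valid at any composition.

Fitting a lipid-containing titration with a model that ignores the lipid
biases the constant by a factor that is independent of the protein
concentration:

```
KeqApp_LW / Keq_LW = 1 / (1 + KP_Lb_LW · α_Lb)          (dilute)
KeqApp_LW / Keq_LW = 1 / (α_W + KP_Lb_LW · α_Lb)        (concentrated media)
```

with `α_Lb = V_Lb/V_T` the lipid volume fraction. The package predicts
this bias, inverts it (apparent → intrinsic), extrapolates
apparent-affinity series to zero lipid, and fits titrations with the
full model, the lipid-neglecting depletion quadratic, or the
excess-ligand hyperbola.

## Worked example

Chlorpromazine binds serum albumin with `Keq_LW ≈ 1e6 M⁻¹` and has a
lipid-bilayer partition coefficient `KP_Lb_LW ≈ 1e4`. Blood plasma
carries about 1% v/v of lipoprotein lipid, so an affinity measured in
plasma while counting lipid-associated drug as free is apparent.
Correcting an apparent `1e4 M⁻¹` back to the intrinsic constant:

```
$ lipidbind correct --keq-app 1e4 --kp 1e4 --alpha-lb 0.01
{
  "keq_lw_per_molar": 1010000.0,
  "keq_app_per_molar": 10000.0,
  "bias_ratio": 0.009900990099009901,
  "fold_decrease": 101.0,
  "orders_decrease": 2.0043213737826426,
  "regime": "dilute"
}
```

The bias ratio `1/(1+10⁴·0.01) ≈ 0.0099` means the lipid costs two
orders of magnitude of apparent affinity; the corrected intrinsic
constant is `1.01e6 M⁻¹`, back at the purified-protein value.

The same machinery solves a full composition. For a 50 kDa protein at
10 µM with `Keq = 1e6 M⁻¹`, ligand lipophilicity `KP = 1e3`, 10 µM total
ligand and 1% lipid:

```
$ lipidbind distribute --log-keq 6 --log-kp 3 --pt 1e-5 --lt 1e-5 --alpha-lb 0.01 --mw 50000
{
  "l_w_molar": 5.709986319874554e-07,
  "l_lb_molar": 5.770110875194076e-06,
  "l_p_molar": 3.6588904928184698e-06,
  ...
  "saturation": 0.36588904928184696
}
```

58% of the ligand sits in the lipid, only 0.06% of the system volume —
which is exactly why neglecting it distorts fitted affinities.

Library use mirrors the CLI (`lipidbind.solve_general`,
`lipidbind.fit`, `lipidbind.bias_dilute`,
`lipidbind.extrapolate_to_zero_lipid`, …); `lipidbind simulate
--scenario fig5` emits the standard simulation tables as CSV, and
`lipidbind synth` generates seeded synthetic titrations.

### Titration CSV format

Header `lt_molar,response`, one row per point; composition metadata
(`pt_molar`, `alpha_lb`, `mw_gmol`, `kp_lb_lw`, `response_kind`) lives
in a sidecar `<stem>.meta.json` next to the CSV.

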