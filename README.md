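# fiberchrom

Mechanistic simulation and parameter determination for **fiber-based
cation-exchange chromatography** of monoclonal antibodies.

Hydrogel-grafted winged-fiber beds are an emerging alternative to packed
resin columns for protein capture: fast mass transfer, high
permeability, low pressure drop.  This package implements the
lumped-pore (transport-dispersive) column model for such beds together
with the complete independent parameter-determination workflow, so that
a bind–wash–gradient-elution cycle can be predicted *a priori* — no
parameter is fitted to the chromatogram being predicted.  It is aimed at
bioprocess modellers and chromatography method developers.

## Model

Mobile and stagnant (hydrogel) phases per species *i*:

    ∂C_i/∂t   = −v ∂C_i/∂z + D_ax ∂²C_i/∂z² − ((1−ε_b)/ε_b)·A·k_eff,i·(C_i − C_f,i)
    ε_p ∂C_f,i/∂t + (1−ε_p) ∂q_i/∂t = A·k_eff,i·(C_i − C_f,i)

with Danckwerts boundary conditions, D_ax = α·v, and local-equilibrium
binding by the salt-dependent multi-component Langmuir isotherm

    q_i = K_i q_max,i C_f,i / (1 + Σ_j K_j C_f,j),
    q_max,i = a1_i·c + a2_i,   K_i = b1_i·e^(−b2_i·c)

(c = NaCl concentration).  Every parameter comes from a separate small
experiment or a correlation:

| parameter | method | module |
|---|---|---|
| ε_T, ε_b, ε_p | inverse size-exclusion chromatography + moment analysis | `moments` |
| α (D_ax = α·v) | tracer pulses at several flow rates | `moments` |
| k_eff, A | fiber geometry + obstruction diffusivity (+ Wilson film) | `mass_transfer` |
| a1, a2, b1, b2 | batch-adsorption isotherms at ≥ 4 salt levels | `isotherms` |
| plant dispersion | column-bypass tracer moments | `system_dispersion` |

A synthetic-data module generates all of these inputs with realistic
noise from a fixed ground truth, so the full chain is testable without
instrument data.

## Worked example

Derive the lumped rate coefficient k_eff,A = (1−ε_b)·A·k_eff for the
reference bed (ε_T = 0.76, ε_b = 0.54, r_F = 7.5 µm) and simulate a
gradient elution:

```python
from fiberchrom import (BedGeometry, Component, FlowProgram, GroundTruth,
                        assemble_system, derive_coefficients, simulate)

bed = BedGeometry()                      # reference bed defaults
for name, D_m in {"NaCl": 1.99e-9, "acetone": 1.14e-9, "mAb": 4.00e-11}.items():
    tc = derive_coefficients(D_m, bed, mode="internal")
    print(f"{name:8s} k_eff,A = {tc.k_eff_A:.3g} 1/s")

truth = GroundTruth()                    # synthetic mAb binding parameters
mab = Component("mAb", 4.00e-11, binding=truth.binding["mAb"])
program = FlowProgram.bind_wash_elute(load={"mAb": 4.0}, gradient_cv=7.5)
res = simulate(assemble_system(bed, [mab], {}, program))
print(res.mass_balance[["species", "fed_mg", "eluted_mg", "closure"]])
```

prints

```
NaCl     k_eff,A = 6.43 1/s
acetone  k_eff,A = 3.68 1/s
mAb      k_eff,A = 0.129 1/s
  species  fed_mg    eluted_mg   closure
0    salt  8380.0  7520.460059  1.000165
1     mAb     0.4     0.400000  1.000000
```

The three rate coefficients span nearly two orders of magnitude purely
through the molecular diffusivity — tracers exchange quickly with the
hydrogel, the antibody slowly — and the 100 µL mAb pulse (0.4 mg) is
fully recovered in the gradient with the species mass balance closed to
machine-level accuracy (the salt row includes the column hold-up
turnover).

## Analysis workflow

Numbered drivers under `analysis/` run the full study on synthetic data
and write tables to `results/`:

1. `01_characterize_bed.py` — iSEC voidages, porosity, dispersivity
2. `02_mass_transfer.py` — k_eff,A per solute, internal vs series film
3. `03_fit_isotherms.py` — salt-dependent Langmuir recovery per component
4. `04_validate_transport.py` — hold-up, dispersion and mass-balance checks
5. `05_gradient_prediction.py` — mAb elution vs gradient length
6. `06_sensitivity_keffA.py` — rate-coefficient sensitivity scan
7. `07_broth_separation.py` — three-class broth elution, fractions,
   composite-assay inversion

A CLI (`fiberchrom simulate|moments|isec|fit-system|masstransfer|`
`fit-isotherm|scan|synth|compare`) exposes the same operations on CSV
and YAML inputs.

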