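# Methods

## Scope and model

`fiberchrom` models bind-and-elute cation-exchange chromatography on a
packed bed of hydrogel-grafted winged fibers.  The bed is treated as a
one-dimensional, radially homogeneous porous medium with a bimodal
structure: interstitial transport channels (voidage ε_b) carrying
convective flow, and a stagnant liquid phase inside the grafted hydrogel
(stationary-phase porosity ε_p).  For each species *i* the lumped-pore
(transport-dispersive) formulation is solved:

    ∂C_i/∂t   = −v ∂C_i/∂z + D_ax ∂²C_i/∂z²
                − ((1−ε_b)/ε_b) · A·k_eff,i · (C_i − C_f,i)

    ε_p ∂C_f,i/∂t + (1−ε_p) ∂q_i/∂t = A·k_eff,i · (C_i − C_f,i)

with Danckwerts boundary conditions (total-flux inlet
v·C(0,t) − D_ax ∂C/∂z = v·C_D(t), zero-gradient outlet) and the column
initially equilibrated in buffer.  Axial dispersion scales with the
interstitial velocity, D_ax = α·v, with the dispersivity α a geometric
bed property.  Salt is species 0: transported and exchanged like any
solute, never bound, and its **local stagnant-phase** concentration
drives the binding parameters of the proteins (binding happens inside the
hydrogel, so the salt the protein experiences is the hydrogel-local one;
the distinction only matters during fast transients).

Binding is local equilibrium with the competitive multi-component
Langmuir isotherm

    q_i = K_i q_max,i C_f,i / (1 + Σ_j K_j C_f,j)

and ion-exchange salt dependence

    q_max,i(c) = a1_i·c + a2_i,      K_i(c) = b1_i·exp(−b2_i·c),

c the modifier (NaCl) concentration in mM.  The index under the
competition sum runs over the *competitor* constants K_j (the standard
competitive form; the single-component case reduces to the textbook
Langmuir).  Rather than integrating a separate kinetic rate for q, the
isotherm is substituted into the stagnant-phase accumulation term:

    [ε_p I + (1−ε_p) ∂q/∂C_f] · dC_f/dt = A·k_eff (C − C_f)

The Jacobian ∂q/∂C_f is analytic and includes the salt column (parameter
drift dq/dc through a1, b2), so salt transients propagate consistently
into the bound phase.  The n×n system (n = number of species, typically
2–4) is solved per grid cell at every right-hand-side evaluation.

## Parameter determination workflow

Every transport parameter is obtained independently of the
chromatographic cycle, mirroring the bench workflow:

* **Moments.**  First and second temporal moments of tracer peaks by
  trapezoidal quadrature, with linear baseline correction anchored on
  declared pre/post windows and integration limited to the contiguous
  region above 0.1% of the peak maximum (moments are tail-sensitive; the
  truncation rule is explicit and configurable, `threshold_frac=0`
  recovers plain quadrature).  Extra-column contributions subtract
  moment-wise (series convolution).
* **iSEC.**  Accessible volume fraction ε = F·μ_p/V per tracer size.
  The printed form of this relation (ε = VF/μ) is dimensionally
  inconsistent; the implementation uses the reading under which a tracer
  accessing all liquid (μ = V/F) gives ε = 1.  Small-tracer and
  large-tracer plateaus give ε_T and ε_b; ε_p = (ε_T − ε_b)/(1 − ε_b).
* **Dispersivity.**  D_ax = σ_p²·v³/(2L) per velocity, then an
  origin-forced regression D_ax = α·v (a free-intercept fit is reported
  as a diagnostic only).  The σ²-based estimate assumes a hold-up-free
  tracer; the validation suite therefore uses a stagnant-phase-excluded
  tracer (k_eff,A = 0, the iSEC large-tracer experiment).  A fully
  accessing tracer in the fast-exchange limit would return
  D_ax·(1+k0)², k0 the hold-up factor.
* **Mass transfer.**  1/k_eff = 1/k_ext + 1/k_int.  External film from
  the Wilson packed-bed correlation Sh = (1.09/ε_b)·Sc^0.33·Re^0.33
  (superficial velocity and fiber diameter in Re; validity
  0.0015 < Re < 55, extrapolation warns).  Internal coefficient from the
  mean diffusive path r_F/2 through the channel-filling hydrogel,
  k_int = 2·D_eff/r_F, with the Mackie–Meares obstruction factor
  D_eff = D_m·(ε_p/(2−ε_p))².  The obstruction model is behind a named
  strategy (`deff_model`) so an ε_p/(2−ε_p) porosity–tortuosity variant
  can be swapped in; Mackie–Meares is the default because it is the
  standard choice for diffusion in swollen polymer meshes and is the one
  consistent with the reference bed's tabulated rate coefficients.
  Specific exchange area A = 2/r_F (cylindrical fiber); the BET-derived
  area is exposed only as a labelled upper bound.  Default lumping mode
  is **internal-controlled** (k_eff = k_int): for this bed the hydrogel
  resistance dominates for proteins, and the correlation-based external
  film is kept as an optional series resistance (`mode="series"`).
* **Isotherms.**  Per-salt-level Langmuir regressions
  (`scipy.optimize.curve_fit`, non-negative bounds, initial q_max at
  1.2× the largest q and K from the initial slope), then q_max vs salt
  by ordinary linear least squares and K vs salt log-linearly when all
  K > 0 (variance stabilisation for an exponential law; nonlinear
  fallback otherwise).  Composite assay readouts for clarified broth
  (affinity total-mAb; size-exclusion monomer/aggregate/contaminants)
  invert by linear least squares over the three lumped classes, with the
  affinity-vs-size-exclusion total reported against a declared
  consistency tolerance.

## Extra-column (plant) dispersion

The plant is reduced to a plug-flow dead volume plus n identical mixed
tanks, identified by moment matching of a column-bypass tracer
(μ = (V_delay + n·V_mix)/F, σ² = n·(V_mix/F)²; n chosen as the largest
integer leaving a non-negative delay).  Forward application is a delay
shift plus a bin-integrated gamma-kernel convolution (area-preserving,
moment-exact to quadrature tolerance).  By default the identified volume
is split 50/50 before/after the column (configurable); no plant volumes
are assumed by default because none were measured here.

## Numerics

Finite volumes in z, method of lines.  The default face scheme is
**central differencing** for convection plus central dispersion: at the
default grid (N = 200 cells, L = 3 cm) the cell Péclet number
v·Δz/D_ax = Δz/α ≈ 0.3 is far below the stability bound of 2, and the
scheme is second order, so the numerical dispersion that a first-order
upwind face would add (D_num ≈ v·Δz/2, ~15% of α·v at this grid) is
absent.  Upwind remains selectable for steep-front robustness.  Time
integration uses banded LSODA (bandwidth 2n from per-cell interleaved
ordering), rtol 1e-6 / atol 1e-9.  Grid convergence at the defaults:
halving the cell count changes gradient-elution retention by < 0.01% and
peak width by < 0.1%.  A run aborts if any concentration drops below
−1e-3 relative to its field maximum (advice: refine the grid).  Mass
balance is reported per species as (eluted + final hold-up)/(fed +
initial hold-up); the discrete scheme conserves mass exactly up to
integration tolerance, and a full bind/wash/gradient cycle closes to
better than 0.1%.

Degenerate inputs: all-zero batch isotherm data return a flagged
non-binding result (K = 0, q_max undetermined); q_max(c) < 0 over the
declared salt range of a program is a configuration error at assembly
(never silently clipped — the solver clips only sub-roundoff transients);
zero-variance plant moments degrade to a pure delay.

## Synthetic data: what it emulates, what it does not

The generator produces every input the pipeline consumes, using the
forward model itself for chromatograms (so estimation stages are tested
against internally consistent truth): batch-adsorption designs (default
5 concentrations × 4 salt levels, 2% multiplicative Gaussian noise on
q), tracer pulses (additive Gaussian detector noise), iSEC curves (a
log-radius smoothstep partition function between full hydrogel access
and complete exclusion, exact plateaus at ε_T and ε_b), and
three-class broth elutions with 400 µL fraction tables and composite
assay readouts.  Bed defaults are the reference characterization
(ε_T = 0.76, ε_b = 0.54, α = 0.051 cm, r_F = 7.5 µm, L = 3 cm,
d = 1 cm, V = 2.36 mL); diffusivities are the tabulated reference
values.

The protein binding parameters are **fixtures, not measured values** (no
fitted set was ever published for this system): monomer/mAb
(a1, a2, b1, b2) = (−0.10, 65, 5.0, 0.025), aggregates with b1 = 5.8 and
a slower D_m, contaminant class (−0.04, 30, 4.0, 0.015) — chosen once to
give a mid-gradient mAb elution, near co-elution of monomer and
aggregates, and later elution of the contaminant class.  b2 = 0.025/mM
corresponds to a Yamamoto-type characteristic charge of ~4–7 in the
100–200 mM range, a realistic steepness for a mAb on a cation exchanger.
Consequences worth knowing: passing round-trip tests shows the
estimation chain is unbiased under the assumed noise models, not that
real detector drift, calibration error, or charge-variant heterogeneity
are handled; and with a realistically steep salt dependence the
simulated gradient peaks are sharper than the reference system's
experimental ones, so the mass-transfer coefficient remains mildly
visible in peak width up to ~5 1/s instead of becoming numerically
invisible above 1 1/s (the qualitative ordering — strong sensitivity
below 1 1/s, progressive insensitivity above — is reproduced).

## Problem sizes

Default resolutions were chosen so a full gradient cycle integrates in
under a second and the entire validation suite in well under a minute:
N = 200 cells for quantitative runs, N = 100 in unit tests where 0.5%
accuracy suffices, 1200–1500 output samples per run, 8–20 seeds for
Monte-Carlo recovery checks.

## Known limitations

* No radial gradients, surface/solid diffusion, or pH dependence; buffer
  chemistry is reduced to the NaCl modifier concentration.
* The multi-component Langmuir with unequal q_max is used as-is
  (thermodynamic consistency corrections out of scope).
* The plant model is a declared stand-in (delay + tanks-in-series); real
  fittings may need more structure than two moments identify.
* Column overload/frontal operation is untested; validation pulses are
  100 µL at 4 mg/mL (far from saturation).
* The Wilson film correlation extrapolates poorly outside
  0.0015 < Re < 55 and is bypassed entirely in the default
  internal-controlled mode.
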