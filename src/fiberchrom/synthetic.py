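"""Synthetic study data with the statistical structure the pipeline assumes.

Every input the estimation and simulation stages consume can be generated
here: batch-adsorption points on the salt-dependent Langmuir surface,
non-binding tracer pulses (produced by the forward column model itself, so
moment-recovery tests are internally consistent), inverse size-exclusion
accessible-fraction curves with their two plateaus, and full
three-component gradient elutions of a synthetic clarified broth with
400 µL fraction tables and composite (affinity / size-exclusion style)
assay readouts.

The generator defaults ARE the reference study conditions: the bed from
the characterization summary (eps_T 0.76, eps_b 0.54, alpha 0.051 cm,
r_F 7.5 µm, L 3 cm, d 1 cm), the printed molecular diffusivities, batch
designs of five concentrations by four salt levels, 100 µL injections at
3 mL/min.  Binding parameters for the synthetic proteins are fixtures
(the study never printed its fitted values); they are chosen once to give
the qualitative behaviour of a weak-partitioning mAb feed: monomer and
aggregates nearly co-eluting mid-gradient, low-molecular-weight
contaminants eluting at higher salt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotherms import BROTH_CLASSES, SaltDependence, eval_salt_dependence
from .solver import (
    FlowProgram,
    SolverSettings,
    assemble_system,
    simulate,
)
from .system_dispersion import SystemModel
from .types import BedGeometry, Chromatogram, Component

#: Molecular diffusivities (m²/s) of the reference solutes.
DEFAULT_DM = {
    "NaCl": 1.99e-9,
    "acetone": 1.14e-9,
    "mAb": 4.00e-11,
}

#: Salt-dependent Langmuir fixtures for the synthetic feed components
#: (q_max = a1*c + a2 in mg/mL, K = b1*exp(-b2*c) in mL/mg, c in mM).
DEFAULT_BINDING = {
    "mAb": SaltDependence(a1=-0.10, a2=65.0, b1=5.0, b2=0.025),
    "monomer": SaltDependence(a1=-0.10, a2=65.0, b1=5.0, b2=0.025),
    "aggregate": SaltDependence(a1=-0.10, a2=65.0, b1=5.8, b2=0.025),
    "lowMW": SaltDependence(a1=-0.04, a2=30.0, b1=4.0, b2=0.015),
}

#: Diffusivities for the broth classes: aggregates somewhat slower than the
#: monomer, small contaminants faster.
BROTH_DM = {"monomer": 4.00e-11, "aggregate": 3.0e-11, "lowMW": 1.0e-10}


@dataclass(frozen=True)
class GroundTruth:
    """Fixed truth used by all generators (bed, solutes, noise levels)."""

    bed: BedGeometry = field(default_factory=BedGeometry)
    D_m: dict = field(default_factory=lambda: dict(DEFAULT_DM, **BROTH_DM))
    binding: dict = field(default_factory=lambda: dict(DEFAULT_BINDING))
    detector_sigma: float = 0.002  # additive, signal units
    batch_sigma: float = 0.02  # multiplicative, relative
    isec_sigma: float = 0.004  # additive on accessible fraction
    isec_r_full_nm: float = 1.5  # largest radius with full hydrogel access
    isec_r_excl_nm: float = 11.0  # smallest fully excluded radius

    def __post_init__(self):
        for name in ("detector_sigma", "batch_sigma", "isec_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise level {name} must be >= 0")


def gen_batch_dataset(
    truth: GroundTruth,
    component: str = "mAb",
    salt_levels=(20.0, 60.0, 100.0, 140.0),
    conc_grid=(0.25, 0.5, 1.0, 2.0, 5.0),
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy batch-adsorption records on the salt-dependent Langmuir surface.

    Defaults mirror the reference design: five equilibrium concentrations
    (0–5 mg/mL range) at four salt levels, 2% multiplicative noise on q.
    Returns a frame with columns component, c_eq_mg_ml, q_mg_ml, salt_mM.
    """
    if len(salt_levels) == 0 or len(conc_grid) == 0:
        raise ValueError("salt_levels and conc_grid must be non-empty")
    rng = np.random.default_rng(seed)
    sd = truth.binding[component]
    rows = []
    for c_mod in salt_levels:
        p = eval_salt_dependence(sd, float(c_mod))
        for _ in range(replicates):
            for c in conc_grid:
                q = p.K_eq * p.q_max * c / (1.0 + p.K_eq * c)
                q_noisy = q * (1.0 + truth.batch_sigma * rng.standard_normal())
                rows.append(
                    {
                        "component": component,
                        "c_eq_mg_ml": float(c),
                        "q_mg_ml": max(float(q_noisy), 0.0),
                        "salt_mM": float(c_mod),
                    }
                )
    return pd.DataFrame(rows)


def gen_tracer_peak(
    truth: GroundTruth,
    species: str = "acetone",
    F_ml_min: float = 3.0,
    seed: int = 0,
    *,
    injection_ml: float = 0.1,
    concentration: float = 1.0,
    system_model: SystemModel | None = None,
    k_eff_A: float | None = None,
    settings: SolverSettings | None = None,
    noise: bool = True,
) -> Chromatogram:
    """Non-binding tracer pulse generated by the forward column model.

    ``k_eff_A=None`` derives the coefficient from the species diffusivity;
    pass 0 for a stagnant-phase-excluded tracer.  Additive Gaussian
    detector noise (``truth.detector_sigma``) is applied unless disabled.
    """
    rng = np.random.default_rng(seed)
    program = FlowProgram.tracer_pulse(
        species=species, F_ml_min=F_ml_min, injection_ml=injection_ml,
        concentration=concentration,
    )
    comps = [Component(species, D_m=truth.D_m[species])]
    coeffs = {} if k_eff_A is None else {species: k_eff_A}
    system = assemble_system(
        truth.bed, comps, coeffs, program,
        settings=settings or SolverSettings(),
        system_model=system_model,
    )
    res = simulate(system)
    chrom = res.outlet
    if noise and truth.detector_sigma > 0:
        noisy = {
            k: v + truth.detector_sigma * rng.standard_normal(v.shape)
            for k, v in chrom.data.items()
        }
        chrom = Chromatogram(chrom.time_s, noisy)
    return chrom


def gen_isec_curve(
    truth: GroundTruth,
    r_h_grid=None,
    seed: int = 0,
    *,
    F_ml_min: float = 1.0,
) -> pd.DataFrame:
    """Accessible-volume-fraction curve over tracer hydrodynamic radius.

    eps(r_H) = eps_b + (eps_T - eps_b) * phi(r_H), where the partition
    function phi is a smoothstep in log10(r_H): exactly 1 below
    ``isec_r_full_nm`` (full hydrogel access, small-tracer plateau eps_T)
    and exactly 0 above ``isec_r_excl_nm`` (complete exclusion,
    large-tracer plateau eps_b).  Returns a frame with columns r_h_nm,
    epsilon, mu_s (the first moment V*eps/F an instrument would record at
    flow F).
    """
    if r_h_grid is None:
        r_h_grid = np.geomspace(0.5, 20.0, 15)
    r = np.asarray(r_h_grid, dtype=float)
    rng = np.random.default_rng(seed)
    bed = truth.bed
    lo, hi = np.log10(truth.isec_r_full_nm), np.log10(truth.isec_r_excl_nm)
    s = np.clip((np.log10(r) - lo) / (hi - lo), 0.0, 1.0)
    phi = 1.0 - (3.0 * s**2 - 2.0 * s**3)
    eps = bed.eps_b + (bed.eps_T - bed.eps_b) * phi
    eps_noisy = np.clip(eps + truth.isec_sigma * rng.standard_normal(r.shape), 0.0, 1.0)
    mu_s = eps_noisy * bed.V_ml / (F_ml_min / 60.0)
    return pd.DataFrame({"r_h_nm": r, "epsilon": eps_noisy, "mu_s": mu_s})


def gen_broth_elution(
    truth: GroundTruth,
    program: FlowProgram | None = None,
    seed: int = 0,
    *,
    load=None,
    fraction_ml: float = 0.4,
    settings: SolverSettings | None = None,
    system_model: SystemModel | None = None,
    noise: bool = True,
):
    """Three-component gradient elution of a synthetic clarified broth.

    ``load`` maps class name to injected concentration (default monomer
    2.0, aggregate 0.2, lowMW 1.0 mg/mL — aggregates at 10% of the monomer
    load).  Returns ``(chromatogram, fraction_table, composites)``:

    * outlet chromatogram (detector noise optional),
    * per-fraction masses integrated over ``fraction_ml`` windows,
    * per-fraction composite assay readouts (total-mAb = monomer +
      aggregate, plus the class-resolved size-exclusion values).
    """
    rng = np.random.default_rng(seed)
    load = dict(load or {"monomer": 2.0, "aggregate": 0.2, "lowMW": 1.0})
    program = program or FlowProgram.bind_wash_elute(gradient_cv=10.0, load=load)
    comps = [
        Component(name, D_m=truth.D_m[name], binding=truth.binding[name])
        for name in BROTH_CLASSES
    ]
    system = assemble_system(
        truth.bed, comps, {}, program,
        settings=settings or SolverSettings(), system_model=system_model,
    )
    res = simulate(system)
    chrom = res.column_outlet if system_model is None else res.outlet

    # --- fractionation: cumulative eluted mass interpolated at the exact
    # fixed-volume window edges (conserves the integrated outlet mass)
    t = chrom.time_s
    F_ml_s = np.array([system.flow_at(tt) for tt in t]) / 60.0
    vol = np.concatenate([[0.0], np.cumsum(0.5 * (F_ml_s[1:] + F_ml_s[:-1]) * np.diff(t))])
    edges = np.arange(0.0, vol[-1] + fraction_ml, fraction_ml)
    rows = []
    cum = {}
    for cls in BROTH_CLASSES:
        rate = chrom.signal(cls) * F_ml_s
        cum[cls] = np.concatenate(
            [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))]
        )
    for k in range(len(edges) - 1):
        row = {"fraction": k, "volume_start_ml": edges[k], "volume_end_ml": edges[k + 1]}
        for cls in BROTH_CLASSES:
            m0 = np.interp(edges[k], vol, cum[cls])
            m1 = np.interp(edges[k + 1], vol, cum[cls])
            row[f"{cls}_mg"] = float(m1 - m0)
        rows.append(row)
    fractions = pd.DataFrame(rows)

    # --- composite assay readouts per fraction (mean concentration basis)
    widths = fractions["volume_end_ml"] - fractions["volume_start_ml"]
    comp = pd.DataFrame(
        {
            "fraction": fractions["fraction"],
            "total_mab": (fractions["monomer_mg"] + fractions["aggregate_mg"]) / widths,
            "monomer": fractions["monomer_mg"] / widths,
            "aggregate": fractions["aggregate_mg"] / widths,
            "lowMW": fractions["lowMW_mg"] / widths,
        }
    )
    if noise and truth.detector_sigma > 0:
        noisy = {
            k: v + truth.detector_sigma * rng.standard_normal(v.shape)
            for k, v in chrom.data.items()
        }
        chrom = Chromatogram(chrom.time_s, noisy)
    return chrom, fractions, comp
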