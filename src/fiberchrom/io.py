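"""Configuration parsing, chromatogram CSV I/O, run comparison, manifests.

Config files are YAML (or JSON, a YAML subset) with blocks ``bed``,
``components``, optional ``coefficients``, ``program``, optional
``system`` and ``solver``, and an optional ``seed``.  Unknown keys are
rejected and every error names the offending dotted key.  CSV dialect:
comma-separated, '.' decimal, UTF-8, mandatory header; chromatograms have
a leading ``time_s`` column and one column per species.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .isotherms import LangmuirParams, SaltDependence
from .moments import peak_moments
from .solver import (
    ColumnSystem,
    FlowProgram,
    Segment,
    SolverSettings,
    assemble_system,
)
from .system_dispersion import SystemModel
from .types import BedGeometry, Chromatogram, Component

_BED_KEYS = {"L_cm", "d_col_cm", "V_ml", "eps_T", "eps_b", "eps_p", "alpha_cm", "r_F_um"}
_BED_REQUIRED = {"eps_T", "eps_b", "eps_p"}
_COMP_KEYS = {"name", "D_m", "binding"}
_SEG_KEYS = {"duration", "duration_unit", "F_ml_min", "inlet", "inlet_end", "label"}
_SYSTEM_KEYS = {"V_delay_ml", "V_mix_ml", "n_tanks", "split"}
_SOLVER_KEYS = {"n_cells", "scheme", "method", "rtol", "atol", "n_out", "negative_tol",
                "store_fields"}
_TOP_KEYS = {"bed", "components", "coefficients", "program", "system", "solver", "seed"}


@dataclass
class RunConfig:
    """Validated run configuration (parsed domain objects + the raw mapping)."""

    bed: BedGeometry
    components: list
    coefficients: dict
    program: FlowProgram
    settings: SolverSettings
    system_model: SystemModel | None
    system_split: float
    seed: int
    raw: dict = field(repr=False, default_factory=dict)

    def assemble(self) -> ColumnSystem:
        return assemble_system(
            self.bed, self.components, self.coefficients, self.program,
            settings=self.settings, system_model=self.system_model,
            system_split=self.system_split,
        )


def _reject_unknown(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def parse_config(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigurationError("config root must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "config root")
    for req in ("bed", "components", "program"):
        if req not in doc:
            raise ConfigurationError(f"missing config block {req!r}")

    bed_block = dict(doc["bed"])
    _reject_unknown(bed_block, _BED_KEYS, "bed")
    for key in _BED_REQUIRED:
        if key not in bed_block:
            raise ConfigurationError(f"missing key 'bed.{key}' (dimensionless porosity)")
    bed = BedGeometry(**bed_block)

    components = []
    seen = set()
    for i, c in enumerate(doc["components"]):
        c = dict(c)
        _reject_unknown(c, _COMP_KEYS, f"components[{i}]")
        for key in ("name", "D_m"):
            if key not in c:
                raise ConfigurationError(f"missing key 'components[{i}].{key}'")
        if c["name"] in seen:
            raise ConfigurationError(f"component {c['name']!r} defined more than once")
        seen.add(c["name"])
        binding = c.get("binding")
        if binding is not None:
            b = dict(binding)
            if set(b) == {"q_max", "K_eq"}:
                binding = LangmuirParams(**b)
            elif set(b) == {"a1", "a2", "b1", "b2"}:
                binding = SaltDependence(**b)
            else:
                raise ConfigurationError(
                    f"components[{i}].binding must have keys (q_max, K_eq) "
                    f"[mg/mL, mL/mg] or (a1, a2, b1, b2), got {sorted(b)}"
                )
        components.append(Component(c["name"], float(c["D_m"]), binding))

    coefficients = dict(doc.get("coefficients") or {})
    for name in coefficients:
        if name not in seen and name != "salt":
            raise ConfigurationError(f"coefficients name {name!r} matches no component")

    segments = []
    for i, s in enumerate(doc["program"]):
        s = dict(s)
        _reject_unknown(s, _SEG_KEYS, f"program[{i}]")
        for key in ("duration", "F_ml_min", "inlet"):
            if key not in s:
                raise ConfigurationError(f"missing key 'program[{i}].{key}'")
        segments.append(Segment(**s))
    program = FlowProgram(tuple(segments))

    system_model, split = None, 0.5
    if doc.get("system"):
        s = dict(doc["system"])
        _reject_unknown(s, _SYSTEM_KEYS, "system")
        split = float(s.pop("split", 0.5))
        system_model = SystemModel(**s)

    solver_block = dict(doc.get("solver") or {})
    _reject_unknown(solver_block, _SOLVER_KEYS, "solver")
    settings = SolverSettings(**solver_block)

    return RunConfig(
        bed=bed,
        components=components,
        coefficients=coefficients,
        program=program,
        settings=settings,
        system_model=system_model,
        system_split=split,
        seed=int(doc.get("seed", 0)),
        raw=doc,
    )


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=False)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.raw, sort_keys=True, default=float)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(path, config: RunConfig | None = None, seed: int | None = None,
                   extra: dict | None = None) -> None:
    """Record what produced a run's outputs (config hash, seed, version)."""
    from . import __version__

    manifest = {"package": "fiberchrom", "version": __version__}
    if config is not None:
        manifest["config_sha256"] = config_hash(config)
        manifest["seed"] = config.seed if seed is None else seed
    elif seed is not None:
        manifest["seed"] = seed
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=float) + "\n")


# ---------------------------------------------------------------------------
# Chromatogram CSV
# ---------------------------------------------------------------------------

def read_chromatogram(path) -> Chromatogram:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise DataError(f"{path}: chromatogram CSV must have a 'time_s' header column")
    try:
        return Chromatogram.from_frame(df)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_chromatogram(chrom: Chromatogram, path) -> None:
    chrom.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run comparison
# ---------------------------------------------------------------------------

def compare_runs(sim: Chromatogram, ref: Chromatogram, species: str | None = None) -> dict:
    """Compare a simulated against a reference chromatogram on a common grid.

    Returns R² of the overlaid signals, the peak-position offset (s), the
    peak-width (FWHM) ratio and the mass (area) ratio, sim relative to ref.
    """
    if species is None:
        shared = [s for s in sim.species if s in ref.species]
        if not shared:
            raise DataError("no shared species between the two chromatograms")
        species = shared[0]
    lo = max(sim.time_s[0], ref.time_s[0])
    hi = min(sim.time_s[-1], ref.time_s[-1])
    if hi <= lo:
        raise DataError("chromatogram time ranges do not overlap")
    t = np.linspace(lo, hi, 2000)
    ys = np.interp(t, sim.time_s, sim.signal(species))
    yr = np.interp(t, ref.time_s, ref.signal(species))
    ss_tot = float(np.sum((yr - yr.mean()) ** 2))
    r2 = 1.0 - float(np.sum((ys - yr) ** 2)) / ss_tot if ss_tot > 0 else 1.0

    from .solver import _fwhm

    ms = peak_moments(t, ys)
    mr = peak_moments(t, yr)
    return {
        "species": species,
        "r2": r2,
        "peak_offset_s": float(t[np.argmax(ys)] - t[np.argmax(yr)]),
        "width_ratio": _fwhm(t, ys) / _fwhm(t, yr),
        "mass_ratio": ms.area / mr.area,
    }
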