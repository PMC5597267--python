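"""Core containers: bed geometry, solute components and chromatograms.

Practical bench units are used at the container surface (cm, mL, mL/min,
µm, mg/mL, mM) because that is how columns and methods are specified;
SI conversions are exposed as properties and the solver works in SI
internally (m, s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DataError, DomainError


@dataclass(frozen=True)
class BedGeometry:
    """Geometry and porosity set of a packed fiber bed.

    Parameters
    ----------
    L_cm : bed length (cm).
    d_col_cm : inner column diameter (cm).
    V_ml : column volume (mL); must agree with ``pi (d/2)^2 L`` within 0.5%.
    eps_T : total liquid-accessible volume fraction (interstitial + hydrogel).
    eps_b : interstitial (between-fiber) voidage carrying convective flow.
    eps_p : hydrogel volume fraction of the stationary phase.
    alpha_cm : dispersivity, the slope of D_ax = alpha * v (cm).
    r_F_um : fiber radius (µm).
    """

    L_cm: float = 3.0
    d_col_cm: float = 1.0
    V_ml: float = 2.36
    eps_T: float = 0.76
    eps_b: float = 0.54
    eps_p: float = 0.478260869565
    alpha_cm: float = 0.051
    r_F_um: float = 7.5

    def __post_init__(self):
        if not (0.0 < self.eps_b < self.eps_T < 1.0):
            raise DomainError(
                f"voidage ordering violated: need 0 < eps_b < eps_T < 1, "
                f"got eps_b={self.eps_b}, eps_T={self.eps_T}"
            )
        if not (0.0 < self.eps_p < 1.0):
            raise DomainError(f"eps_p must lie in (0, 1), got {self.eps_p}")
        if self.alpha_cm < 0:
            raise DomainError(f"dispersivity alpha must be >= 0, got {self.alpha_cm}")
        if self.r_F_um <= 0 or self.L_cm <= 0 or self.d_col_cm <= 0:
            raise DomainError("bed dimensions must be positive")
        v_geom = math.pi * (self.d_col_cm / 2.0) ** 2 * self.L_cm
        if abs(self.V_ml - v_geom) / v_geom > 0.005:
            raise DataError(
                f"column volume {self.V_ml} mL inconsistent with geometry "
                f"pi*(d/2)^2*L = {v_geom:.4f} mL (tolerance 0.5%)"
            )

    # --- SI views -----------------------------------------------------
    @property
    def L_m(self) -> float:
        return self.L_cm * 1e-2

    @property
    def area_m2(self) -> float:
        """Column cross-sectional area (m^2)."""
        return math.pi * (self.d_col_cm * 1e-2 / 2.0) ** 2

    @property
    def V_m3(self) -> float:
        return self.V_ml * 1e-6

    @property
    def r_F_m(self) -> float:
        return self.r_F_um * 1e-6

    @property
    def alpha_m(self) -> float:
        return self.alpha_cm * 1e-2

    def interstitial_velocity(self, F_ml_min: float) -> float:
        """Interstitial velocity v = F / (A_col * eps_b), in m/s."""
        return F_ml_min * 1e-6 / 60.0 / (self.area_m2 * self.eps_b)

    def superficial_velocity(self, F_ml_min: float) -> float:
        """Superficial velocity u = F / A_col, in m/s."""
        return F_ml_min * 1e-6 / 60.0 / self.area_m2


@dataclass(frozen=True)
class Component:
    """A solute species transported through the column.

    ``binding`` is ``None`` for non-binding species (tracers, salt);
    otherwise a fixed :class:`~fiberchrom.isotherms.LangmuirParams` or a
    salt-dependent :class:`~fiberchrom.isotherms.SaltDependence`.
    """

    name: str
    D_m: float  # molecular diffusivity, m^2/s
    binding: Optional[object] = None

    def __post_init__(self):
        if not (self.D_m > 0 and math.isfinite(self.D_m)):
            raise DomainError(f"component {self.name!r}: D_m must be positive, got {self.D_m}")

    @property
    def non_binding(self) -> bool:
        return self.binding is None


class Chromatogram:
    """A time series of concentrations/signals per species at one plane.

    Wraps a monotone time axis (s) and a mapping of species name to signal
    array.  The time grid may be irregular; operations that need a uniform
    grid resample explicitly.
    """

    def __init__(self, time_s: np.ndarray, data: Mapping[str, np.ndarray]):
        t = np.asarray(time_s, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise DataError("chromatogram needs a 1-D time axis with >= 2 points")
        if np.any(np.diff(t) <= 0):
            raise DataError("chromatogram time axis must be strictly increasing")
        self.time_s = t
        self.data = {}
        for name, y in data.items():
            arr = np.asarray(y, dtype=float)
            if arr.shape != t.shape:
                raise DataError(
                    f"signal {name!r} has length {arr.size}, time axis has {t.size}"
                )
            self.data[str(name)] = arr

    @property
    def species(self):
        return list(self.data)

    def signal(self, name: str) -> np.ndarray:
        return self.data[name]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, **self.data})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Chromatogram":
        if "time_s" not in df.columns:
            raise DataError("chromatogram table must have a 'time_s' column")
        cols = [c for c in df.columns if c != "time_s"]
        if not cols:
            raise DataError("chromatogram table has no signal columns")
        return cls(df["time_s"].to_numpy(), {c: df[c].to_numpy() for c in cols})

    def resample(self, time_s: np.ndarray) -> "Chromatogram":
        """Linear-interpolation resampling onto a new grid (0 outside support)."""
        t = np.asarray(time_s, dtype=float)
        return Chromatogram(
            t,
            {k: np.interp(t, self.time_s, v, left=0.0, right=0.0) for k, v in self.data.items()},
        )

    def shifted(self, dt: float) -> "Chromatogram":
        return Chromatogram(self.time_s + dt, dict(self.data))

    def __repr__(self):
        return (
            f"Chromatogram({self.time_s.size} points, "
            f"t = [{self.time_s[0]:g}, {self.time_s[-1]:g}] s, species {self.species})"
        )
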