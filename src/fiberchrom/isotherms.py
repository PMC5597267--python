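"""Salt-dependent multi-component Langmuir binding: evaluation and fitting.

The adsorption equilibrium between the stagnant fluid and the ligand sites
on a cation-exchange hydrogel is described by the competitive Langmuir
isotherm

    q_i = K_i * qmax_i * C_i / (1 + sum_j K_j * C_j)

with the salt (modifier) dependence of the parameters

    qmax_i(c) = a1_i * c + a2_i          (linear)
    K_i(c)    = b1_i * exp(-b2_i * c)    (exponential decay)

where ``c`` is the NaCl concentration in mM.  Concentrations are mg/mL,
bound amounts mg per mL of stationary phase.

Fitting goes the way the bench workflow does: per-salt-level Langmuir
regressions first, then regression of the resulting (qmax, K) sets against
salt.  For complex feeds (clarified cell culture broth) the assay readouts
are linear composites of the three lumped classes (monomer, aggregates,
low-molecular-weight contaminants); ``invert_composite`` recovers class
pseudo-concentrations from those readouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigurationError, DomainError, EstimationError, RangeError

BROTH_CLASSES = ("monomer", "aggregate", "lowMW")


@dataclass(frozen=True)
class LangmuirParams:
    """Single-component Langmuir parameter pair.

    q_max : maximum binding capacity, mg per mL stationary phase.
    K_eq  : equilibrium binding constant, mL/mg.
    """

    q_max: float
    K_eq: float

    def __post_init__(self):
        if not (math.isfinite(self.q_max) and math.isfinite(self.K_eq)):
            raise DomainError("Langmuir parameters must be finite")
        if self.q_max < 0 or self.K_eq < 0:
            raise DomainError(
                f"Langmuir parameters must be >= 0, got q_max={self.q_max}, K_eq={self.K_eq}"
            )


@dataclass(frozen=True)
class SaltDependence:
    """Salt dependence of a component's Langmuir parameters.

    a1 : slope of q_max vs salt (mg mL^-1 mM^-1), typically <= 0.
    a2 : q_max at zero salt (mg/mL).
    b1 : K_eq at zero salt (mL/mg).
    b2 : exponential decay rate of K_eq with salt (1/mM).
    """

    a1: float
    a2: float
    b1: float
    b2: float

    def __post_init__(self):
        for name in ("a1", "a2", "b1", "b2"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"salt-dependence parameter {name} must be finite")
        if self.b1 < 0 or self.b2 < 0:
            raise DomainError(f"need b1 >= 0 and b2 >= 0, got b1={self.b1}, b2={self.b2}")

    def evaluate(self, c_mod: float) -> LangmuirParams:
        """Langmuir parameters at salt concentration ``c_mod`` (mM)."""
        return eval_salt_dependence(self, c_mod)

    def validate_range(self, c_max: float, c_min: float = 0.0) -> None:
        """Check q_max >= 0 over the declared salt range [c_min, c_max]."""
        for c in (c_min, c_max):
            if self.a1 * c + self.a2 < 0:
                raise RangeError(
                    f"q_max = a1*c + a2 is negative ({self.a1 * c + self.a2:.4g} mg/mL) "
                    f"at salt level {c:g} mM"
                )


def eval_salt_dependence(sd: SaltDependence, c_mod: float) -> LangmuirParams:
    """Evaluate the linear/exponential salt laws at one salt level (mM)."""
    if c_mod < 0:
        raise DomainError(f"salt concentration must be >= 0, got {c_mod}")
    q_max = sd.a1 * c_mod + sd.a2
    if q_max < 0:
        raise RangeError(f"q_max evaluates negative ({q_max:.4g} mg/mL) at c_mod = {c_mod:g} mM")
    return LangmuirParams(q_max=q_max, K_eq=sd.b1 * math.exp(-sd.b2 * c_mod))


def eval_langmuir(params: Sequence[LangmuirParams], C_f) -> np.ndarray:
    """Competitive multi-component Langmuir bound amounts.

    Parameters
    ----------
    params : one :class:`LangmuirParams` per component.
    C_f : per-component stagnant-phase concentrations, mg/mL (array-like).

    Returns per-component bound amounts q_f (mg/mL stationary phase).
    """
    C = np.asarray(C_f, dtype=float)
    if C.shape != (len(params),):
        raise DomainError(f"expected {len(params)} concentrations, got shape {C.shape}")
    if np.any(C < 0):
        raise DomainError(f"concentrations must be >= 0, got {C}")
    K = np.array([p.K_eq for p in params])
    qmax = np.array([p.q_max for p in params])
    denom = 1.0 + float(K @ C)
    return K * qmax * C / denom


def fit_langmuir(C_eq, q, *, p0=None) -> tuple[LangmuirParams, float, bool]:
    """Nonlinear least-squares Langmuir regression q = K*qmax*C/(1+K*C).

    Returns ``(params, r_squared, binding)``.  ``binding`` is False for
    degenerate all-zero data, in which case K_eq = 0 and q_max is reported
    as 0 (undetermined).
    """
    C = np.asarray(C_eq, dtype=float)
    Q = np.asarray(q, dtype=float)
    if C.size != Q.size or C.size < 3:
        raise EstimationError("Langmuir fit needs >= 3 (C_eq, q) points")
    if np.ptp(C) == 0:
        raise EstimationError("Langmuir fit needs distinct C_eq values")
    if np.any(C < 0) or np.any(Q < 0):
        raise DomainError("batch adsorption data must be non-negative")
    if np.all(Q == 0):
        return LangmuirParams(q_max=0.0, K_eq=0.0), 1.0, False

    def model(c, qmax, k):
        return k * qmax * c / (1.0 + k * c)

    if p0 is None:
        qmax0 = 1.2 * Q.max()
        # initial slope K*qmax estimated from the lowest-concentration point
        i = np.argmax(C > 0)
        k0 = max(Q[i] / C[i], 1e-6) / qmax0
        p0 = (qmax0, k0)
    try:
        popt, _ = curve_fit(
            model, C, Q, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - non-convergence path
        raise EstimationError(f"Langmuir regression did not converge: {exc}", last_iterate=p0)
    resid = Q - model(C, *popt)
    ss_tot = float(np.sum((Q - Q.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return LangmuirParams(q_max=float(popt[0]), K_eq=float(popt[1])), r2, True


def fit_salt_dependence(
    fits: Iterable[tuple[float, LangmuirParams]]
) -> tuple[SaltDependence, dict]:
    """Regress per-salt-level Langmuir parameters against salt concentration.

    q_max vs c is fitted by ordinary linear least squares; K_eq vs c by
    log-linear regression when all K_eq > 0 (variance stabilisation for an
    exponential law), otherwise by nonlinear least squares.

    Returns the :class:`SaltDependence` and a dict of per-regression R².
    """
    pairs = sorted(fits, key=lambda t: t[0])
    if len(pairs) < 3:
        raise EstimationError("salt-dependence regression needs >= 3 distinct salt levels")
    c = np.array([p[0] for p in pairs], dtype=float)
    if np.unique(c).size < 3:
        raise EstimationError("salt-dependence regression needs >= 3 distinct salt levels")
    qmax = np.array([p[1].q_max for p in pairs])
    keq = np.array([p[1].K_eq for p in pairs])

    a1, a2 = np.polyfit(c, qmax, 1)
    r2_q = _r_squared(qmax, a1 * c + a2)

    if np.all(keq > 0):
        slope, intercept = np.polyfit(c, np.log(keq), 1)
        b1, b2 = math.exp(intercept), -slope
        r2_k = _r_squared(np.log(keq), slope * c + intercept)
    else:
        popt, _ = curve_fit(
            lambda x, b1, b2: b1 * np.exp(-b2 * x),
            c,
            keq,
            p0=(max(keq.max(), 1e-6), 0.01),
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
        b1, b2 = popt
        r2_k = _r_squared(keq, b1 * np.exp(-b2 * c))
    # a flat K(c) can regress to a tiny negative slope under noise; K decay
    # rates are physically >= 0
    b2 = max(float(b2), 0.0)
    sd = SaltDependence(a1=float(a1), a2=float(a2), b1=float(b1), b2=b2)
    return sd, {"r2_qmax": r2_q, "r2_keq": r2_k}


def _r_squared(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum((y - np.asarray(yhat)) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# Batch adsorption datasets
# ---------------------------------------------------------------------------

#: Fiber packing density of the reference bed, g fiber per mL column volume;
#: converts bound amounts measured per gram of fiber to per mL of bed.
PACKING_DENSITY_G_PER_ML = 0.35

BATCH_COLUMNS = ("component", "c_eq_mg_ml", "q_mg_ml", "salt_mM")


class BatchAdsorptionDataset:
    """Equilibrium batch-adsorption records (C_eq, q, c_mod) per component.

    Backed by a :class:`pandas.DataFrame` with columns
    ``component, c_eq_mg_ml, q_mg_ml, salt_mM``.  ``q`` is mg per mL
    stationary phase; data measured per gram of dry fiber are converted on
    construction via a declared packing density (g/mL).
    """

    def __init__(self, frame, *, q_per_gram: bool = False,
                 packing_density: float = PACKING_DENSITY_G_PER_ML):
        import pandas as pd

        df = pd.DataFrame(frame).copy()
        missing = [c for c in BATCH_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"batch dataset missing columns: {missing}")
        df = df[list(BATCH_COLUMNS)]
        if q_per_gram:
            df["q_mg_ml"] = df["q_mg_ml"] * packing_density
        if (df["c_eq_mg_ml"] < 0).any() or (df["q_mg_ml"] < 0).any():
            raise DomainError("batch adsorption data must be non-negative")
        self.frame = df

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BatchAdsorptionDataset":
        import pandas as pd

        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def subset(self, component: str, salt_mM: float | None = None) -> "BatchAdsorptionDataset":
        df = self.frame[self.frame["component"] == component]
        if salt_mM is not None:
            df = df[np.isclose(df["salt_mM"], salt_mM)]
        return BatchAdsorptionDataset(df)

    def salt_levels(self, component: str) -> np.ndarray:
        return np.unique(self.frame.loc[self.frame["component"] == component, "salt_mM"])

    def fit_component(self, component: str) -> tuple[SaltDependence, dict]:
        """Per-salt Langmuir fits followed by the salt-dependence regression.

        Each salt level must contribute >= 3 concentration points.  Returns
        the fitted :class:`SaltDependence` and a report holding the per-level
        Langmuir fits and regression R² values.
        """
        levels = self.salt_levels(component)
        per_level = []
        for c_mod in levels:
            sub = self.subset(component, c_mod).frame
            if len(sub) < 3:
                raise EstimationError(
                    f"component {component!r}, salt {c_mod:g} mM: need >= 3 points, "
                    f"have {len(sub)}"
                )
            params, r2, binding = fit_langmuir(sub["c_eq_mg_ml"], sub["q_mg_ml"])
            per_level.append((float(c_mod), params, r2, binding))
        sd, r2s = fit_salt_dependence([(c, p) for c, p, _, _ in per_level])
        report = {
            "per_level": per_level,
            **r2s,
        }
        return sd, report


# ---------------------------------------------------------------------------
# Composite assay inversion for clarified broth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositeMeasurement:
    """One assay readout expressed as a linear composite of broth classes.

    ``weights`` maps class name (monomer | aggregate | lowMW) to a
    non-negative coefficient; ``value`` is the readout in IgG-equivalent
    mg/mL (a pseudo-concentration for the contaminant class).
    """

    assay: str
    value: float
    weights: Mapping[str, float]

    def __post_init__(self):
        for k, w in self.weights.items():
            if k not in BROTH_CLASSES:
                raise ConfigurationError(f"unknown broth class {k!r} in assay {self.assay!r}")
            if w < 0:
                raise ConfigurationError(f"assay {self.assay!r}: weights must be >= 0")


#: Conventional assay weight rows: affinity (Protein A) capture sees all mAb
#: (monomer + aggregate); size exclusion resolves the three classes.
STANDARD_ASSAYS = {
    "total-mAb": {"monomer": 1.0, "aggregate": 1.0},
    "monomer": {"monomer": 1.0},
    "aggregate": {"aggregate": 1.0},
    "lowMW": {"lowMW": 1.0},
}


def invert_composite(
    measurements: Sequence[CompositeMeasurement], *, tolerance: float = 0.1
) -> tuple[dict, dict]:
    """Least-squares inversion of composite assay readouts to class concentrations.

    Returns ``(concentrations, report)`` where ``concentrations`` maps the
    three class names to recovered pseudo-concentrations and ``report``
    carries the residual norm plus, when both an affinity total and the
    size-exclusion monomer/aggregate pair are present, the total-vs-sum
    inconsistency checked against ``tolerance`` (mg/mL).
    """
    if not measurements:
        raise ConfigurationError("no composite measurements given")
    W = np.array(
        [[m.weights.get(cls, 0.0) for cls in BROTH_CLASSES] for m in measurements]
    )
    y = np.array([m.value for m in measurements], dtype=float)
    if np.linalg.matrix_rank(W) < len(BROTH_CLASSES):
        raise ConfigurationError(
            "assay weight matrix is rank deficient over (monomer, aggregate, lowMW); "
            "add assays that resolve all three classes"
        )
    x, res, _, _ = np.linalg.lstsq(W, y, rcond=None)
    conc = dict(zip(BROTH_CLASSES, (float(v) for v in x)))
    report = {"residual_norm": float(np.linalg.norm(W @ x - y))}
    by_assay = {m.assay: m.value for m in measurements}
    if {"total-mAb", "monomer", "aggregate"} <= set(by_assay):
        inconsistency = abs(by_assay["total-mAb"] - by_assay["monomer"] - by_assay["aggregate"])
        report["total_mab_inconsistency"] = float(inconsistency)
        report["consistent"] = bool(inconsistency <= tolerance)
    return conc, report
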