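"""Statistical-moment analysis of tracer peaks and iSEC characterization.

A narrow tracer pulse carries the bed's hold-up and dispersion in its first
and second temporal moments:

    mu      = int C(t) t dt / int C(t) dt
    sigma^2 = int C(t) (t - mu)^2 dt / int C(t) dt

Extra-column (plant) contributions subtract moment-wise because the column
and the plant act in series (convolution).  From corrected moments follow
the accessible volume fraction eps = F * mu / V (inverse size-exclusion
chromatography), the axial dispersion coefficient D_ax = sigma^2 v^3 / (2L),
and the dispersivity alpha as the origin-forced slope of D_ax vs v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DomainError, EstimationError
from .types import Chromatogram


@dataclass(frozen=True)
class PeakMoments:
    """First moment (s), second central moment (s²) and area (signal·s)."""

    mu: float
    sigma2: float
    area: float

    def __post_init__(self):
        if not self.area > 0:
            raise DomainError(f"peak area must be > 0, got {self.area}")
        if self.sigma2 < 0:
            raise DomainError(f"second central moment must be >= 0, got {self.sigma2}")


def baseline_correct(
    t: np.ndarray, y: np.ndarray, pre_window: tuple[float, float], post_window: tuple[float, float]
) -> np.ndarray:
    """Subtract a linear baseline anchored on pre- and post-peak windows.

    The baseline is the straight line through the mean (t, y) of each
    window.  Values driven negative by the subtraction are clipped at zero
    (moments are tail-sensitive; a noise floor must not contribute).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    anchors = []
    for lo, hi in (pre_window, post_window):
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise DataError(f"baseline window [{lo}, {hi}] contains no samples")
        anchors.append((t[mask].mean(), y[mask].mean()))
    (t0, y0), (t1, y1) = anchors
    slope = (y1 - y0) / (t1 - t0) if t1 != t0 else 0.0
    corrected = y - (y0 + slope * (t - t0))
    return np.clip(corrected, 0.0, None)


def peak_moments(
    chrom_or_t, y=None, *, species: str | None = None, threshold_frac: float = 1e-3
) -> PeakMoments:
    """Trapezoidal first/second temporal moments of a baseline-corrected peak.

    Accepts either ``(Chromatogram, species=...)`` or raw ``(t, y)`` arrays.
    Integration is restricted to the contiguous region where the signal
    exceeds ``threshold_frac`` of the peak maximum, so that an instrumental
    noise floor far from the peak cannot dominate the variance.
    """
    if isinstance(chrom_or_t, Chromatogram):
        chrom = chrom_or_t
        if species is None:
            if len(chrom.species) != 1:
                raise DataError("species must be named for a multi-species chromatogram")
            species = chrom.species[0]
        t, y = chrom.time_s, chrom.signal(species)
    else:
        t = np.asarray(chrom_or_t, dtype=float)
        y = np.asarray(y, dtype=float)

    if np.all(y == 0):
        raise DomainError("all-zero signal has no defined moments")
    if y.min() < 0 and abs(y.min()) > 1e-12 * max(y.max(), 1e-300):
        y = np.clip(y, 0.0, None)

    if threshold_frac > 0:
        cut = threshold_frac * y.max()
        above = np.flatnonzero(y > cut)
        lo, hi = above[0], above[-1]
        sl = slice(max(lo - 1, 0), min(hi + 2, len(t)))
        t, y = t[sl], y[sl]

    area = float(np.trapezoid(y, t))
    if area <= 0:
        raise DomainError(f"peak area must be positive, got {area}")
    mu = float(np.trapezoid(y * t, t)) / area
    sigma2 = float(np.trapezoid(y * (t - mu) ** 2, t)) / area
    return PeakMoments(mu=mu, sigma2=max(sigma2, 0.0), area=area)


def correct_extra_column(obs: PeakMoments, system: PeakMoments | None) -> PeakMoments:
    """Subtract extra-column (plant) moments from observed column moments.

    Valid because column and plant broadening act in series: moments of a
    convolution add.  ``system=None`` (or zero moments) is the identity.
    """
    if system is None:
        return obs
    mu = obs.mu - system.mu
    sigma2 = obs.sigma2 - system.sigma2
    if mu < 0 or sigma2 < 0:
        raise DataError(
            "column signal narrower than the extra-column system signal: "
            f"corrected (mu, sigma2) = ({mu:.4g}, {sigma2:.4g})"
        )
    # area is a calibration quantity, untouched by a volume correction
    return PeakMoments(mu=mu, sigma2=sigma2, area=obs.area)


def accessible_fraction(mu_p_s: float, F_ml_min: float, V_ml: float) -> float:
    """Accessible volume fraction eps = F * mu / V from an iSEC first moment.

    ``mu_p_s`` in seconds, ``F_ml_min`` in mL/min, ``V_ml`` in mL.  A tracer
    accessing the whole liquid volume has mu = V/F and eps = 1; values above
    1.05 indicate inconsistent data and raise.
    """
    if mu_p_s <= 0 or F_ml_min <= 0 or V_ml <= 0:
        raise DomainError("accessible_fraction needs positive mu, F and V")
    eps = (F_ml_min / 60.0) * mu_p_s / V_ml
    if eps > 1.05:
        raise DataError(
            f"accessible fraction {eps:.3f} > 1.05: first moment exceeds the "
            "column residence volume — check F, V or the extra-column correction"
        )
    return eps


def porosity_from_voidages(eps_T: float, eps_b: float) -> float:
    """Stationary-phase porosity eps_p = (eps_T - eps_b) / (1 - eps_b)."""
    if not (0.0 < eps_b <= eps_T <= 1.0):
        raise DomainError(
            f"need 0 < eps_b <= eps_T <= 1, got eps_b={eps_b}, eps_T={eps_T}"
        )
    return (eps_T - eps_b) / (1.0 - eps_b)


def dax_from_moments(sigma2: float, v: float, L: float) -> float:
    """Axial dispersion D_ax = sigma^2 * v^3 / (2 L).

    Units are the caller's (consistent): sigma2 in s², v in length/s, L in
    the same length unit; D_ax comes back in length²/s.  Valid for a tracer
    excluded from the stagnant phase (hold-up-free residence).
    """
    if sigma2 < 0 or v <= 0 or L <= 0:
        raise DomainError("dax_from_moments needs sigma2 >= 0 and positive v, L")
    return sigma2 * v**3 / (2.0 * L)


def fit_dispersivity(pairs) -> tuple[float, dict]:
    """Origin-forced least-squares slope alpha of D_ax = alpha * v.

    ``pairs`` is an iterable of (v, D_ax).  Returns ``(alpha, report)``
    where the report carries R² of the forced fit and, as a diagnostic
    only, the free-intercept slope/intercept.
    """
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise EstimationError("dispersivity regression needs >= 2 (v, D_ax) pairs")
    v, dax = data[:, 0], data[:, 1]
    denom = float(v @ v)
    if denom == 0:
        raise EstimationError("dispersivity regression needs non-zero velocities")
    alpha = float(v @ dax) / denom
    ss_tot = float(np.sum((dax - dax.mean()) ** 2))
    ss_res = float(np.sum((dax - alpha * v) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    report = {"r2": r2}
    if data.shape[0] >= 2 and np.ptp(v) > 0:
        slope, intercept = np.polyfit(v, dax, 1)
        report["free_fit"] = {"slope": float(slope), "intercept": float(intercept)}
    return alpha, report


def voidages_from_isec(
    r_h_nm, eps, *, small_r_max_nm: float = 1.0, large_r_min_nm: float = 12.0
) -> tuple[float, float]:
    """Plateau extraction from an iSEC accessible-fraction curve.

    The small-tracer plateau (r_H <= ``small_r_max_nm``) estimates the total
    voidage eps_T; the large-tracer plateau (r_H >= ``large_r_min_nm``) the
    interstitial voidage eps_b.  Returns ``(eps_T, eps_b)`` as plateau means.
    """
    r = np.asarray(r_h_nm, dtype=float)
    e = np.asarray(eps, dtype=float)
    if np.any((e < -0.05) | (e > 1.05)):
        raise DataError("accessible fractions must lie in [0, 1] (5% noise band allowed)")
    small = e[r <= small_r_max_nm]
    large = e[r >= large_r_min_nm]
    if small.size == 0 or large.size == 0:
        raise DataError(
            f"iSEC grid must span both plateaus: need points with r_H <= "
            f"{small_r_max_nm} nm and >= {large_r_min_nm} nm"
        )
    eps_T = float(small.mean())
    eps_b = float(large.mean())
    if eps_b >= eps_T:
        raise DataError(f"plateau ordering violated: eps_b={eps_b:.3f} >= eps_T={eps_T:.3f}")
    return eps_T, eps_b
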