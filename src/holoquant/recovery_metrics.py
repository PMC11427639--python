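"""Evaluation statistics for quantified phantom volumes.

Covers the activity-concentration recovery coefficient (ACRC), axial
activity-concentration profiles (ACPs), cumulative activity-volume
histograms (cAVHs), 3-parameter logistic recovery curves

    ACRC(d) = a * (1 - 1 / (1 + (d/b)**c)),

and the region-based partial-volume correction they support. The
logistic's ``a`` is the large-diameter asymptote (highest achievable
ACRC), ``b`` the diameter at half that asymptote and ``c`` the
steepness; ACRC(b) = a/2 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .phantom_geometry import PhantomSpec
from .quantification import QuantifiedVolume
from .volumes import ActivityVolume, VOIMask

__all__ = [
    "RecoveryCurveFit",
    "ProfileResult",
    "CAVH",
    "acrc",
    "activity_profiles",
    "cavh",
    "fit_recovery_curve",
    "apply_pvc",
    "logistic_recovery",
    "RecoveryFitError",
]


def logistic_recovery(d, a, b, c):
    """3-parameter logistic recovery model evaluated at diameter(s) d (mm)."""
    d = np.asarray(d, dtype=float)
    return a * (1.0 - 1.0 / (1.0 + (d / b) ** c))


class RecoveryFitError(RuntimeError):
    """Raised when the logistic fit fails; carries the best attempt found."""

    def __init__(self, message: str, best: "RecoveryCurveFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class RecoveryCurveFit:
    """Fitted recovery curve: parameters, uncertainty and goodness of fit."""

    a: float
    b: float
    c: float
    r2: float
    covariance: np.ndarray
    diameters_mm: tuple[float, ...] = ()
    acrc_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"fit parameters must be positive, got {(self.a, self.b, self.c)}")

    def predict(self, d):
        return logistic_recovery(d, self.a, self.b, self.c)

    def param_se(self) -> tuple[float, float, float]:
        """Standard errors of (a, b, c) from the fit covariance."""
        se = np.sqrt(np.clip(np.diag(np.asarray(self.covariance, dtype=float)), 0, None))
        return tuple(se)  # type: ignore[return-value]

    def summary(self) -> str:
        se = self.param_se()
        lines = [
            "Recovery curve  ACRC(d) = a (1 - 1/(1 + (d/b)^c))",
            f"  a (asymptote)        {self.a:8.4f}  (se {se[0]:.4f})",
            f"  b (half-max d, mm)   {self.b:8.3f}  (se {se[1]:.3f})",
            f"  c (steepness)        {self.c:8.3f}  (se {se[2]:.3f})",
            f"  R^2                  {self.r2:8.5f}",
            f"  n points             {len(self.diameters_mm):5d}",
        ]
        return "\n".join(lines)


@dataclass
class ProfileResult:
    """Activity-concentration profile along the phantom symmetry axis."""

    positions_mm: np.ndarray
    values: np.ndarray
    descriptor: str  # "row(x,y)" or "radius r"
    edge_margin_mm: float
    interior: np.ndarray  # bool: slices further than margin from phantom ends

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("profile positions must be strictly increasing")

    def percent_of_true_range(self, ac_true: float) -> tuple[float, float]:
        """(min, max) percent of the true concentration over interior slices."""
        vals = self.values[self.interior]
        if vals.size == 0:
            raise ValueError("no profile slices inside the edge margin")
        return (100.0 * vals.min() / ac_true, 100.0 * vals.max() / ac_true)


@dataclass
class CAVH:
    """Cumulative activity-volume histogram (empirical survival function)."""

    thresholds: np.ndarray  # MBq/mL, increasing
    fractions: np.ndarray  # fraction of VOI volume with value >= threshold

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be non-decreasing")


def _values_of(vol) -> tuple:
    if isinstance(vol, QuantifiedVolume):
        return vol.grid, vol.values
    if isinstance(vol, ActivityVolume):
        return vol.grid, vol.values
    raise TypeError(f"expected a quantified or activity volume, got {type(vol)}")


def acrc(qvol, voi: VOIMask, ac_true: float) -> float:
    """Activity concentration recovery coefficient: VOI mean over truth."""
    if not ac_true > 0:
        raise ValueError("true activity concentration must be positive")
    grid, values = _values_of(qvol)
    if grid != voi.grid:
        raise ValueError("volume and VOI are on different grids")
    if voi.n_voxels == 0:
        raise ValueError(f"VOI '{voi.label}' is empty")
    return float(values[voi.mask].mean()) / ac_true


def activity_profiles(
    qvol,
    phantom: PhantomSpec,
    rows: list[tuple[float, float]] = (),
    radii: list[float] = (),
    margin_mm: float = 30.0,
    axis: int = 2,
) -> list[ProfileResult]:
    """Axial activity-concentration profiles through a cylindrical phantom.

    ``rows`` are (x, y) world positions of single voxel-row profiles;
    ``radii`` give cylindrical-VOI profiles obtained by averaging all
    voxels within that radius of the axis, per slice. Summaries exclude
    slices within ``margin_mm`` of the phantom ends.
    """
    grid, values = _values_of(qvol)
    if axis != 2:
        raise ValueError("profiles are implemented along grid axis 2")
    r_body = phantom.body_diameter_mm / 2.0
    z = grid.axis_coords(2)
    half_h = phantom.body_height_mm / 2.0
    in_phantom = np.abs(z) <= half_h
    interior = np.abs(z) <= half_h - margin_mm
    results: list[ProfileResult] = []
    for x, y in rows:
        if float(np.hypot(x, y)) >= r_body:
            raise ValueError(f"row position ({x}, {y}) lies outside the phantom")
        ix = int(np.round((x - grid.origin[0]) / grid.spacing[0]))
        iy = int(np.round((y - grid.origin[1]) / grid.spacing[1]))
        prof = values[ix, iy, :]
        results.append(
            ProfileResult(z[in_phantom], prof[in_phantom], f"row({x:g},{y:g})",
                          margin_mm, interior[in_phantom])
        )
    xs = grid.axis_coords(0)[:, None]
    ys = grid.axis_coords(1)[None, :]
    rho2 = xs * xs + ys * ys
    for r in radii:
        if r > r_body:
            raise ValueError(f"profile radius {r} mm exceeds phantom radius {r_body} mm")
        disk = rho2 <= r * r
        prof = values[disk, :].mean(axis=0)
        results.append(
            ProfileResult(z[in_phantom], prof[in_phantom], f"radius {r:g} mm",
                          margin_mm, interior[in_phantom])
        )
    return results


def cavh(qvol, voi: VOIMask, thresholds: np.ndarray | None = None, n_levels: int = 256) -> CAVH:
    """Cumulative activity-volume histogram over a VOI.

    With no explicit thresholds, ``n_levels`` evenly spaced levels from 0
    to 1.05x the VOI maximum are used. For a perfectly homogeneous VOI
    the curve is a step function dropping from 1 to 0 at the true value.
    """
    grid, values = _values_of(qvol)
    if grid != voi.grid:
        raise ValueError("volume and VOI are on different grids")
    if voi.n_voxels == 0:
        raise ValueError(f"VOI '{voi.label}' is empty")
    vals = np.sort(values[voi.mask])
    if thresholds is None:
        top = 1.05 * max(float(vals[-1]), 0.0)
        thresholds = np.linspace(0.0, top if top > 0 else 1.0, n_levels)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0):
        raise ValueError("thresholds must be >= 0")
    n_ge = vals.size - np.searchsorted(vals, thresholds, side="left")
    return CAVH(thresholds, n_ge / vals.size)


def fit_recovery_curve(
    diameters_mm,
    acrc_means,
    acrc_sds=None,
    weighted: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
) -> RecoveryCurveFit:
    """Least-squares fit of the 3-parameter logistic recovery curve.

    Initialized at a0 = max ACRC, b0 = median diameter, c0 = 2, with
    jittered restarts; bounds a in (0, 1.5], b in (0, 200] mm, c in
    (0, 10]. Unweighted by default; with ``weighted`` the residuals are
    scaled by 1/sd. R^2 is 1 - SS_res/SS_tot about the mean.
    """
    d = np.asarray(diameters_mm, dtype=float)
    y = np.asarray(acrc_means, dtype=float)
    if d.size != y.size:
        raise ValueError("diameters and ACRC values must have equal length")
    if d.size < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    if np.any(d <= 0) or len(set(d.tolist())) != d.size:
        raise ValueError("diameters must be positive and distinct")
    sigma = None
    if weighted:
        if acrc_sds is None:
            raise ValueError("weighted fit requires acrc_sds")
        sigma = np.asarray(acrc_sds, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("standard deviations must be positive for weighting")
    lo, hi = [1e-9, 1e-9, 1e-9], [1.5, 200.0, 10.0]
    p0_base = np.array([min(max(y.max(), 1e-3), 1.5), float(np.median(d)), 2.0])
    rng = np.random.default_rng(seed)
    best = None
    best_ss = np.inf
    last_err: Exception | None = None
    for k in range(n_restarts):
        p0 = p0_base if k == 0 else np.clip(
            p0_base * rng.uniform(0.5, 1.5, size=3), lo, hi
        )
        try:
            popt, pcov = curve_fit(
                logistic_recovery, d, y, p0=p0, sigma=sigma,
                bounds=(lo, hi), maxfev=20000,
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
            continue
        ss = float(np.sum((y - logistic_recovery(d, *popt)) ** 2))
        if ss < best_ss:
            best_ss = ss
            best = (popt, pcov)
    if best is None:
        raise RecoveryFitError(f"recovery-curve fit did not converge: {last_err}")
    popt, pcov = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_ss / ss_tot if ss_tot > 0 else 1.0
    return RecoveryCurveFit(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), r2=r2,
        covariance=np.asarray(pcov), diameters_mm=tuple(d), acrc_values=tuple(y),
    )


def apply_pvc(
    measured_mean: float,
    diameter_mm: float,
    fit: RecoveryCurveFit,
    floor: float = 0.05,
) -> float:
    """Region-based partial-volume correction: divide by the fitted ACRC.

    Valid only for region means; corrected values must not be used for
    voxel-level assessment. Corrections below ``floor`` recovery are
    refused as numerically unstable.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    rc = float(fit.predict(diameter_mm))
    if rc < floor:
        raise ValueError(
            f"recovery {rc:.4f} at d={diameter_mm} mm is below the stability floor {floor}"
        )
    return measured_mean / rc
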