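"""Conversion-factor quantification of SPECT count volumes.

A count volume is converted to a count-rate density (cps/mL) and divided
by a conversion factor

    CF = (mu / (t * n * V_voxel)) / (A / V_VOI)   [(cps/mL) / (MBq/mL)]

where mu is the mean counts in a calibration VOI, t the projection time
(s), n the number of projections, V_voxel the voxel volume (mL), A the
true activity in the VOI (MBq) and V_VOI its volume (mL). Two ways of
choosing the calibration VOI are implemented:

* scanner-specific ("homogeneous"): a ~2 L cylindrical VOI centered in a
  separately scanned homogeneous phantom with known activity;
* self-calibration ("self"): a VOI encompassing the whole imaged
  phantom together with the total activity present at scan start. By
  construction this method always recovers 100% of the total activity.

Quantified volumes are decay-corrected back to the injection time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_spect import HO166_HALF_LIFE_H, CountVolume
from .volumes import ActivityVolume, VOIMask

__all__ = [
    "ConversionFactor",
    "QuantifiedVolume",
    "compute_cf",
    "self_calibration_cf",
    "quantify_with_cf",
    "recovered_activity_percent",
]


@dataclass(frozen=True)
class ConversionFactor:
    """A conversion factor with the ingredients that produced it.

    ``value`` is in (cps/mL)/(MBq/mL), numerically equal to cps/MBq.
    """

    value: float
    method: str  # homogeneous | self | external_absolute
    voi_label: str = ""
    a_mbq: float = float("nan")
    v_voi_ml: float = float("nan")
    mu_counts: float = float("nan")
    t_s: float = float("nan")
    n_proj: int = 0
    v_voxel_ml: float = float("nan")

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"conversion factor must be positive, got {self.value}")


@dataclass
class QuantifiedVolume:
    """Activity-concentration volume (MBq/mL) decay-corrected to injection."""

    grid: object
    values: np.ndarray
    method: str
    dt_hours: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid shape")

    def as_activity_volume(self) -> ActivityVolume:
        return ActivityVolume(self.grid, self.values, unit="MBq/mL")

    def mean_in(self, voi: VOIMask) -> float:
        return self.as_activity_volume().mean_in(voi)


def compute_cf(
    counts: CountVolume, voi: VOIMask, a_true_mbq: float, method: str = "homogeneous"
) -> ConversionFactor:
    """Conversion factor from a count volume, a VOI and its true activity."""
    if counts.grid != voi.grid:
        raise ValueError("counts and VOI are on different grids")
    if voi.n_voxels == 0:
        raise ValueError(f"VOI '{voi.label}' is empty")
    if not a_true_mbq > 0:
        raise ValueError(f"true activity must be positive, got {a_true_mbq}")
    mu = float(counts.values[voi.mask].mean())
    t, n = counts.meta.t, counts.meta.n
    v_vox = counts.grid.voxel_volume_ml
    value = (mu / (t * n * v_vox)) / (a_true_mbq / voi.volume_ml)
    return ConversionFactor(
        value=value,
        method=method,
        voi_label=voi.label,
        a_mbq=a_true_mbq,
        v_voi_ml=voi.volume_ml,
        mu_counts=mu,
        t_s=t,
        n_proj=n,
        v_voxel_ml=v_vox,
    )


def self_calibration_cf(
    counts: CountVolume, whole_voi: VOIMask, a_at_scan_start_mbq: float
) -> ConversionFactor:
    """Self-calibration CF: whole-phantom VOI and total activity at scan start."""
    return compute_cf(counts, whole_voi, a_at_scan_start_mbq, method="self")


def quantify_with_cf(
    counts: CountVolume,
    cf: ConversionFactor,
    dt_hours: float | None = None,
    half_life_hours: float = HO166_HALF_LIFE_H,
) -> QuantifiedVolume:
    """Quantify a count volume to MBq/mL and decay-correct to injection.

    Each voxel becomes ``(counts / (t n V_voxel)) / CF * 2**(+dt/T_half)``.
    ``dt_hours`` defaults to the acquisition's start offset; pass 0 to
    skip decay correction.
    """
    if dt_hours is None:
        dt_hours = counts.meta.dt_hours
    if half_life_hours <= 0:
        raise ValueError("half-life must be positive")
    rate_density = counts.count_rate_density().values
    corr = 2.0 ** (dt_hours / half_life_hours)
    return QuantifiedVolume(
        grid=counts.grid,
        values=rate_density / cf.value * corr,
        method=cf.method,
        dt_hours=dt_hours,
    )


def recovered_activity_percent(
    qvol: QuantifiedVolume, voi: VOIMask, a_true_injection_mbq: float
) -> float:
    """Percent of the true injected activity recovered in a VOI.

    ``100 * mean(qvol over VOI) * V_VOI / A_true``; for the
    self-calibration method over its own whole-phantom VOI this is 100%
    by construction, independent of noise and dead-time losses.
    """
    if not a_true_injection_mbq > 0:
        raise ValueError("true activity must be positive")
    mean_ac = qvol.mean_in(voi)
    return 100.0 * mean_ac * voi.volume_ml / a_true_injection_mbq
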