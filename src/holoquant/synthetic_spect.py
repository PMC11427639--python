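"""Synthetic SPECT acquisition model.

Stands in for the scanner-plus-reconstruction chain at the reconstructed-
volume level: a ground-truth activity map is blurred with an isotropic
Gaussian point-spread function (finite reconstruction resolution),
scaled to expected counts through the system sensitivity and acquisition
time, attenuated by a single camera-level detection-efficiency factor
from a paralyzable dead-time model, and realized as Poisson counts.

The default acquisition settings follow the study protocol: 2 x 60
projections of 20 s each, Ho-166 half-life 26.8 h, and a 14-time-point
Jaszczak schedule (time points 10, 12, 13 and 14 in triplicate, 22 scans
in total) spanning injection + 1.5 h to + 154.2 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import ActivityVolume, VoxelGrid

__all__ = [
    "HO166_HALF_LIFE_H",
    "JASZCZAK_SCHEDULE_H",
    "CYLINDER_SCAN_DT_H",
    "AcquisitionSpec",
    "DeadTimeModel",
    "CountVolume",
    "ScanResult",
    "decay_activity",
    "apply_psf",
    "apply_dead_time",
    "simulate_acquisition",
    "simulate_schedule",
]

#: Physical half-life of Ho-166 (hours).
HO166_HALF_LIFE_H = 26.8

#: Hours after injection of the 22 Jaszczak scans (triplicates at time
#: points 10, 12, 13 and 14).
JASZCZAK_SCHEDULE_H: tuple[float, ...] = (
    1.5, 5.1, 10.2, 14.6, 24.4, 28.6, 33.5, 37.7, 48.2,
    58.0, 59.2, 60.3,
    75.4,
    81.9, 83.0, 84.1,
    104.8, 105.9, 106.9,
    151.9, 153.1, 154.2,
)

#: Hours after injection of the single homogeneous-cylinder scan
#: (250 MBq of the injected ~311 MBq remained).
CYLINDER_SCAN_DT_H = 8.5


def decay_activity(a0: float, dt_hours: float, half_life_hours: float = HO166_HALF_LIFE_H):
    """Radioactive decay: ``a0 * 2**(-dt/half_life)``.

    Works elementwise on arrays; negative ``dt_hours`` decay-corrects
    backwards in time.
    """
    if half_life_hours <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_hours}")
    return a0 * 2.0 ** (-np.asarray(dt_hours, dtype=float) / half_life_hours)


@dataclass(frozen=True)
class AcquisitionSpec:
    """SPECT acquisition settings.

    Parameters
    ----------
    n : int
        Number of projections (default 120: two heads x 60 stops).
    t : float
        Time per projection in seconds.
    sensitivity : float
        Low-rate system sensitivity in cps per MBq in the field of view.
    psf_fwhm : float
        Isotropic Gaussian PSF full width at half maximum in mm.
    dt_hours : float
        Acquisition start, hours after injection.
    seed : int
        Seed for the Poisson noise stream.
    noise : bool
        If False the expected (non-integer) counts are returned, which
        is convenient for lossless-limit checks.
    """

    n: int = 120
    t: float = 20.0
    sensitivity: float = 19.7
    psf_fwhm: float = 15.0
    dt_hours: float = 0.0
    seed: int = 0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.t <= 0:
            raise ValueError("projection time must be positive")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")

    @property
    def total_time_s(self) -> float:
        return self.t * self.n


@dataclass(frozen=True)
class DeadTimeModel:
    """Paralyzable dead-time: observed = true * exp(-true * tau).

    ``mode="none"`` (or ``tau == 0``) is the identity. ``tau`` is the
    dead-time constant in seconds; the observed rate peaks at a true
    rate of ``1/tau`` and the loss fraction is ``1 - exp(-rate * tau)``.
    """

    tau: float = 0.0
    mode: str = "paralyzable"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.mode not in ("paralyzable", "none"):
            raise ValueError(f"unknown dead-time mode {self.mode!r}")

    @classmethod
    def none(cls) -> "DeadTimeModel":
        return cls(tau=0.0, mode="none")

    @classmethod
    def from_loss_fraction(cls, fraction: float, rate_cps: float) -> "DeadTimeModel":
        """Calibrate tau so the loss fraction at ``rate_cps`` equals ``fraction``.

        Closed form of the paralyzable model: tau = -ln(1 - f) / rate.
        """
        if not 0 <= fraction < 1:
            raise ValueError("loss fraction must be in [0, 1)")
        if rate_cps <= 0:
            raise ValueError("rate must be positive")
        return cls(tau=-math.log(1.0 - fraction) / rate_cps)

    def efficiency(self, true_rate_cps: float) -> float:
        """Detection efficiency g = observed/true at the given true rate."""
        if self.mode == "none" or self.tau == 0.0:
            return 1.0
        return float(np.exp(-np.asarray(true_rate_cps, dtype=float) * self.tau))

    def loss_fraction(self, true_rate_cps: float) -> float:
        return 1.0 - self.efficiency(true_rate_cps)


def apply_dead_time(true_rate_cps, model: DeadTimeModel):
    """Observed count rate after dead-time losses (elementwise)."""
    rate = np.asarray(true_rate_cps, dtype=float)
    if np.any(rate < 0):
        raise ValueError("true count rate must be >= 0")
    if model.mode == "none" or model.tau == 0.0:
        return rate if rate.ndim else float(rate)
    out = rate * np.exp(-rate * model.tau)
    return out if out.ndim else float(out)


def apply_psf(vol: ActivityVolume, fwhm_mm: float) -> ActivityVolume:
    """Isotropic Gaussian blur with sigma = fwhm / (2 sqrt(2 ln 2)) per axis.

    The convolution conserves the volume total provided the field decays
    to zero within ~3 sigma of the grid boundary (zero-padding mode).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_mm = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_vox = [sigma_mm / s for s in vol.grid.spacing]
    blurred = ndimage.gaussian_filter(vol.values, sigma=sigma_vox, mode="constant", cval=0.0)
    return ActivityVolume(vol.grid, blurred, vol.unit)


@dataclass
class CountVolume:
    """Accumulated counts per voxel over one acquisition."""

    grid: VoxelGrid
    values: np.ndarray
    meta: AcquisitionSpec
    efficiency: float = 1.0
    true_total_mbq: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError("counts shape does not match grid shape")

    def count_rate_density(self) -> ActivityVolume:
        """Counts converted to cps/mL: counts / (t * n * V_voxel)."""
        scale = self.meta.t * self.meta.n * self.grid.voxel_volume_ml
        return ActivityVolume(self.grid, self.values / scale, unit="cps/mL")


@dataclass(frozen=True)
class ScanResult:
    """One simulated schedule entry."""

    counts: CountVolume
    dt_hours: float
    true_total_mbq: float
    seed: int


def simulate_acquisition(
    truth: ActivityVolume,
    acq: AcquisitionSpec,
    dead: DeadTimeModel | None = None,
) -> CountVolume:
    """Simulate one SPECT acquisition of a true activity map.

    Expected counts per voxel are ``AC_blurred * V_voxel * sensitivity *
    g * t * n`` where g is the camera-level efficiency evaluated at the
    whole-field true count rate (``total_MBq * sensitivity``). With
    ``acq.noise`` the counts are Poisson-realized from ``acq.seed``;
    identical inputs and seed give bit-identical volumes.
    """
    if dead is None:
        dead = DeadTimeModel.none()
    if np.any(truth.values < 0):
        raise ValueError("truth volume contains negative activity concentrations")
    total_mbq = truth.total
    g = dead.efficiency(total_mbq * acq.sensitivity)
    blurred = apply_psf(truth, acq.psf_fwhm)
    expected = (
        blurred.values
        * truth.grid.voxel_volume_ml
        * acq.sensitivity
        * g
        * acq.t
        * acq.n
    )
    if acq.noise:
        rng = np.random.default_rng(acq.seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return CountVolume(truth.grid, counts, acq, efficiency=g, true_total_mbq=total_mbq)


def simulate_schedule(
    spec,
    schedule_h,
    acq: AcquisitionSpec,
    dead: DeadTimeModel | None = None,
    grid: VoxelGrid | None = None,
    half_life_hours: float = HO166_HALF_LIFE_H,
    supersampling: int = 3,
) -> list[ScanResult]:
    """Simulate a phantom over a decay schedule.

    One acquisition per schedule entry (repeated dts are repeated
    scans). The truth map is voxelized once at injection and scaled by
    ``2**(-dt/T_half)`` per entry; per-entry seeds are ``acq.seed + i``
    so triplicates differ but the run is reproducible.
    """
    from .phantom_geometry import ground_truth_map  # local import, avoids cycle

    schedule = [float(dt) for dt in schedule_h]
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if any(dt < 0 for dt in schedule):
        raise ValueError("schedule entries must be >= 0 hours")
    if grid is None:
        grid = VoxelGrid.centered(spec.body_diameter_mm + 60.0, 4.8)
    truth0 = ground_truth_map(spec, grid, dt_hours=0.0, supersampling=supersampling)
    results = []
    for i, dt in enumerate(schedule):
        factor = float(decay_activity(1.0, dt, half_life_hours))
        truth = ActivityVolume(grid, truth0.values * factor, truth0.unit)
        acq_i = replace(acq, dt_hours=dt, seed=acq.seed + i)
        counts = simulate_acquisition(truth, acq_i, dead)
        results.append(
            ScanResult(counts=counts, dt_hours=dt, true_total_mbq=truth.total, seed=acq_i.seed)
        )
    return results
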