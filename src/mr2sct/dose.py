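"""HU-to-density conversion and a deliberately simplified arc-dose engine.

The engine exists so that dosimetric comparison of synthetic CTs is
exercisable end-to-end; it is a toy, not a treatment planning system:
``n_angles`` coplanar parallel beams arranged in a full arc deposit
``density * exp(-mu * radiological_depth)`` along straight rays, with no
scatter, no beam hardening and no aperture optimization.  Radiological
depth accumulates density times step length along each ray (midpoint
rule, step = half the smallest voxel dimension).  The angular sum is
rescaled so the mean dose over the target mask equals the prescription
exactly, mirroring how clinical plans are normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .volume import Volume

DEFAULT_CURVE_POINTS = ((-1000.0, 0.001), (-100.0, 0.93), (0.0, 1.00),
                        (60.0, 1.06), (1000.0, 1.55), (1500.0, 1.90))


@dataclass
class HUDensityCurve:
    """Piecewise-linear HU -> physical density (g/cc) calibration."""

    points: tuple = DEFAULT_CURVE_POINTS

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("curve needs >= 2 (HU, density) control points")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise ValueError("curve HU values must be strictly increasing")
        if np.any(np.diff(pts[:, 1]) < 0):
            raise ValueError("curve density values must be non-decreasing")
        self._hu = pts[:, 0]
        self._rho = pts[:, 1]


def hu_to_density(hu, curve: HUDensityCurve | None = None):
    """Interpolate density on the calibration curve, clamped at the ends.

    Accepts a scalar, an array, or a :class:`Volume` (returned as an array).
    """
    curve = curve or HUDensityCurve()
    x = hu.data if isinstance(hu, Volume) else hu
    return np.interp(np.asarray(x, dtype=np.float64), curve._hu, curve._rho)


@dataclass
class BeamConfig:
    """Arc geometry, attenuation strength and prescription.

    With ``collimated`` on (the default) each beam's field is shaped to
    the target: a flat aperture covering the target's lateral and
    longitudinal projection plus ``field_margin_mm``, with a Gaussian
    penumbra of width ``penumbra_mm``.  This gives the conformal
    high-dose/low-dose structure of an arc plan; switching it off yields
    unshaped open fields.
    """

    target_mask: Volume = None
    n_angles: int = 36
    mu_per_density: float = 0.005  # attenuation per unit density per mm
    prescription_gy: float = 45.0
    collimated: bool = True
    field_margin_mm: float = 10.0
    penumbra_mm: float = 4.0

    def __post_init__(self):
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.prescription_gy <= 0:
            raise ValueError("prescription_gy must be > 0")
        if self.penumbra_mm <= 0:
            raise ValueError("penumbra_mm must be > 0")


@dataclass
class DoseGrid:
    """Dose values in Gy on a volume grid, with the prescription dose."""

    volume: Volume
    prescription_gy: float

    def __post_init__(self):
        d = np.asarray(self.volume.data)
        if not np.all(np.isfinite(d)):
            raise ValueError("dose values must be finite")
        if np.any(d < 0):
            raise ValueError("dose values must be >= 0")


def compute_dose(ct: Volume, beams: BeamConfig,
                 curve: HUDensityCurve | None = None,
                 normalize: bool = True) -> DoseGrid:
    """Deterministic parallel-beam arc dose on a CT volume.

    For each beam angle the density volume is sampled on a beam-aligned
    in-plane grid, radiological depth is accumulated along the beam axis,
    and each voxel receives ``density * exp(-mu * depth)`` from that
    angle.  The angular sum is normalized so the target-mean dose equals
    ``beams.prescription_gy``.
    """
    curve = curve or HUDensityCurve()
    if beams.target_mask is None:
        raise ValueError("BeamConfig.target_mask is required")
    ct.check_same_grid(beams.target_mask, "ct and target_mask")
    target = np.asarray(beams.target_mask.data) > 0
    if not target.any():
        raise ValueError("target mask is empty")

    density = hu_to_density(ct.data, curve)
    air_rho = float(curve._rho[0])
    nz, ny, nx = ct.shape
    dz, dy, dx = ct.spacing

    def aperture(coord: np.ndarray, lo: float, hi: float) -> np.ndarray:
        """Flat field over [lo, hi] with Gaussian-integrated penumbra."""
        s = beams.penumbra_mm
        return 0.5 * (erf((coord - lo) / (np.sqrt(2.0) * s))
                      - erf((coord - hi) / (np.sqrt(2.0) * s)))

    # in-plane voxel world coordinates relative to the volume centre
    yc = (np.arange(ny) - (ny - 1) / 2) * dy
    xc = (np.arange(nx) - (nx - 1) / 2) * dx
    yy, xx = np.meshgrid(yc, xc, indexing="ij")

    step = min(ct.spacing) / 2.0
    radius = float(np.hypot(yc[-1] - yc[0], xc[-1] - xc[0])) / 2.0 + step
    n_march = int(np.ceil(2 * radius / step))
    n_march += (n_march + 1) % 2  # odd point count keeps the grid symmetric
    uu = np.linspace(-radius, radius, n_march)
    vv = np.linspace(-radius, radius, n_march)
    ug, vg = np.meshgrid(uu, vv, indexing="ij")
    march_h = uu[1] - uu[0]

    # target projections for field shaping (world coords, volume-centred)
    tgt_idx = np.argwhere(target)
    tz = (tgt_idx[:, 0] - (nz - 1) / 2) * dz
    tyx = np.stack([(tgt_idx[:, 1] - (ny - 1) / 2) * dy,
                    (tgt_idx[:, 2] - (nx - 1) / 2) * dx], axis=1)
    zc = (np.arange(nz) - (nz - 1) / 2) * dz
    margin = beams.field_margin_mm
    if beams.collimated:
        z_weight = aperture(zc, tz.min() - margin, tz.max() + margin)
    else:
        z_weight = np.ones(nz)

    dose = np.zeros(ct.shape, dtype=np.float64)
    mu = beams.mu_per_density
    for k in range(beams.n_angles):
        theta = 2.0 * np.pi * k / beams.n_angles
        eu = (np.cos(theta), np.sin(theta))  # beam direction (y, x)
        ev = (-np.sin(theta), np.cos(theta))  # lateral direction
        # beam-frame sample points in world (y, x), then in voxel indices
        py = ug * eu[0] + vg * ev[0]
        px = ug * eu[1] + vg * ev[1]
        ci = (py - yc[0]) / dy
        cj = (px - xc[0]) / dx
        # native-voxel positions on the beam-frame march grid
        u_vox = (yy * eu[0] + xx * eu[1] + radius) / march_h
        v_lat = yy * ev[0] + xx * ev[1]
        v_vox = (v_lat + radius) / march_h
        if beams.collimated:
            tv = tyx @ np.asarray(ev)
            lat_weight = aperture(v_lat, tv.min() - margin, tv.max() + margin)
        else:
            lat_weight = 1.0
        for z in range(nz):
            rho = ndimage.map_coordinates(density[z], [ci, cj], order=1,
                                          mode="constant", cval=air_rho)
            depth = (np.cumsum(rho, axis=0) - 0.5 * rho) * march_h
            d_vox = ndimage.map_coordinates(depth, [u_vox, v_vox], order=1,
                                            mode="nearest")
            dose[z] += z_weight[z] * lat_weight * density[z] * np.exp(-mu * d_vox)

    total = dose[target].mean()
    if total <= 0:
        raise ValueError("zero dose over the target; check inputs")
    if normalize:
        dose *= beams.prescription_gy / total
    vol = Volume(dose.astype(np.float32), ct.spacing, ct.origin, "DOSE")
    return DoseGrid(vol, beams.prescription_gy)
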