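"""Seeded synthetic cohorts of paired MR/CT pelvis-like volumes.

Each phantom is built from a single integer tissue-class map (elliptical
body with a subcutaneous fat ring, two lateral bone structures with
marrow cores, a posterior bone block, a bladder, an adjacent treatment
target, and 0-3 bowel-gas pockets).  CT and MR volumes are rendered from
the same class map — per-class mean plus lightly smoothed Gaussian noise
— so every pair is perfectly aligned by construction.

The MR/CT contrast relations are chosen T2-weighted-like: the bladder is
bright on MR, cortical bone and gas are both dark.  Bone and gas overlap
in MR intensity while sitting at opposite ends of the HU scale, so HU is
deliberately *not* recoverable from MR intensity alone: any single
global monotone MR→HU map must fail, which is what makes the translation
task non-trivial.

Inter-scan intensity drift (gain, offset, smooth multiplicative bias
field, noise) is applied per case by :func:`apply_scan_variation`; it is
the variation that Nyul standardization is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import PairedCase, Volume

#: integer labels of the tissue-class map
CLASS_LABELS = {
    "air": 0,
    "fat": 1,
    "soft_tissue": 2,
    "bladder": 3,
    "bone": 4,
    "marrow": 5,
    "gas": 6,
}
CLASS_NAMES = {v: k for k, v in CLASS_LABELS.items()}

MIN_EXTENT = 16


def _default_hu_mean():
    return {"air": -1000.0, "fat": -90.0, "soft_tissue": 40.0, "bladder": 10.0,
            "bone": 700.0, "marrow": 150.0, "gas": -950.0}


def _default_hu_sd():
    return {"air": 10.0, "fat": 15.0, "soft_tissue": 20.0, "bladder": 15.0,
            "bone": 50.0, "marrow": 30.0, "gas": 15.0}


def _default_mr_mean():
    return {"air": 4.0, "fat": 70.0, "soft_tissue": 45.0, "bladder": 100.0,
            "bone": 10.0, "marrow": 60.0, "gas": 5.0}


def _default_mr_sd():
    return {"air": 2.0, "fat": 5.0, "soft_tissue": 5.0, "bladder": 6.0,
            "bone": 3.0, "marrow": 5.0, "gas": 2.0}


@dataclass
class TissueParams:
    """Per-class intensity statistics and phantom geometry ranges (mm)."""

    hu_mean: dict = field(default_factory=_default_hu_mean)
    hu_sd: dict = field(default_factory=_default_hu_sd)
    mr_mean: dict = field(default_factory=_default_mr_mean)
    mr_sd: dict = field(default_factory=_default_mr_sd)
    # geometry ranges, sampled uniformly per phantom
    body_ry_mm: tuple = (44.0, 52.0)
    body_rx_mm: tuple = (50.0, 58.0)
    fat_thickness_mm: tuple = (6.0, 10.0)
    bone_radius_mm: tuple = (8.0, 12.0)
    bladder_radii_mm: tuple = ((10.0, 16.0), (10.0, 15.0), (10.0, 15.0))
    target_radii_mm: tuple = (12.0, 11.0, 11.0)
    n_gas_range: tuple = (0, 3)
    gas_radius_mm: tuple = (3.5, 7.0)
    noise_smooth_sigma: tuple = (0.5, 0.8, 0.8)

    def validate(self) -> None:
        for d in (self.hu_mean, self.hu_sd, self.mr_mean, self.mr_sd):
            unknown = set(d) - set(CLASS_LABELS)
            if unknown:
                raise ValueError(f"unknown tissue class label(s): {sorted(unknown)}")
            missing = set(CLASS_LABELS) - set(d)
            if missing:
                raise ValueError(f"missing tissue class label(s): {sorted(missing)}")
        hu = self.hu_mean
        if hu["air"] != -1000.0:
            raise ValueError("air hu_mean must be -1000 HU")
        if not (hu["bone"] > hu["soft_tissue"] > hu["fat"] > hu["air"]):
            raise ValueError("HU ordering bone > soft_tissue > fat > air violated")
        # bone vs gas: overlapping MR ranges but disjoint HU ranges
        mr_lo_b = self.mr_mean["bone"] - 3 * self.mr_sd["bone"]
        mr_hi_b = self.mr_mean["bone"] + 3 * self.mr_sd["bone"]
        mr_lo_g = self.mr_mean["gas"] - 3 * self.mr_sd["gas"]
        mr_hi_g = self.mr_mean["gas"] + 3 * self.mr_sd["gas"]
        if mr_lo_b > mr_hi_g or mr_lo_g > mr_hi_b:
            raise ValueError("bone and gas MR ranges must overlap (non-invertibility)")
        if abs(hu["bone"] - hu["gas"]) < 6 * (self.hu_sd["bone"] + self.hu_sd["gas"]):
            raise ValueError("bone and gas HU ranges must be disjoint")


@dataclass
class ScanVariation:
    """Ranges of the per-case MR acquisition drift (sampled uniformly)."""

    gain_range: tuple = (0.7, 1.4)
    offset_range: tuple = (0.0, 8.0)
    bias_amplitude_range: tuple = (0.05, 0.2)
    noise_sd_range: tuple = (1.0, 3.0)


def _ellipsoid(zz, yy, xx, center, radii) -> np.ndarray:
    """Boolean ellipsoid mask; ``center``/``radii`` in mm, broadcast grids."""
    t = 0.0
    for g, c, r in zip((zz, yy, xx), center, radii):
        t = t + ((g - c) / r) ** 2
    return t <= 1.0


def generate_phantom(seed: int, shape: tuple = (16, 64, 64),
                     spacing: tuple = (3.0, 2.0, 2.0),
                     params: TissueParams | None = None) -> PairedCase:
    """Build one aligned MR/CT phantom pair from a seeded tissue-class map.

    Parameters
    ----------
    seed : int
        Seeds both geometry sampling and the rendering noise.
    shape : tuple
        Grid extents ``(nz, ny, nx)``; each must be >= 16.
    spacing : tuple
        Voxel size ``(dz, dy, dx)`` in mm.
    params : TissueParams, optional
        Intensity statistics and geometry ranges.

    Returns
    -------
    PairedCase
        With ``target_mask`` set to the treatment-target ellipsoid.
    """
    if any(s < MIN_EXTENT for s in shape):
        raise ValueError(f"each shape extent must be >= {MIN_EXTENT}, got {shape}")
    params = params or TissueParams()
    params.validate()
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dz, dy, dx = spacing

    z = (np.arange(nz) * dz)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    x = (np.arange(nx) * dx)[None, None, :]
    cz, cy, cx = (nz - 1) * dz / 2, (ny - 1) * dy / 2, (nx - 1) * dx / 2

    U = rng.uniform
    ry = U(*params.body_ry_mm)
    rx = U(*params.body_rx_mm)
    fat_t = U(*params.fat_thickness_mm)
    rbone = U(*params.bone_radius_mm)

    cmap = np.zeros(shape, dtype=np.int16)  # air
    # slight superior-inferior taper so the body outline varies along z
    zhalf = max((nz - 1) * dz / 2.0, 1e-6)
    taper = 1.0 - 0.20 * ((z - cz) / zhalf) ** 2
    body = ((y - cy) / (taper * ry)) ** 2 + ((x - cx) / (taper * rx)) ** 2 <= 1.0
    inner = (((y - cy) / (taper * ry - fat_t)) ** 2
             + ((x - cx) / (taper * rx - fat_t)) ** 2) <= 1.0
    cmap[body] = CLASS_LABELS["fat"]
    cmap[inner] = CLASS_LABELS["soft_tissue"]

    # two lateral bone structures with marrow cores
    rz_bone = 0.8 * (nz * dz) / 2
    for side in (-1.0, 1.0):
        c = (cz, cy + U(-0.05, 0.10) * ry, cx + side * U(0.50, 0.62) * rx)
        bone = _ellipsoid(z, y, x, c, (rz_bone, rbone, rbone)) & inner
        cmap[bone] = CLASS_LABELS["bone"]
        marrow = _ellipsoid(z, y, x, c, (0.6 * rz_bone, 0.55 * rbone, 0.55 * rbone))
        cmap[marrow & bone] = CLASS_LABELS["marrow"]

    # posterior bone block (sacrum stand-in)
    c_sac = (cz, cy + 0.62 * ry, cx)
    sac = _ellipsoid(z, y, x, c_sac, (rz_bone, 0.28 * ry, 0.30 * rx)) & inner
    cmap[sac] = CLASS_LABELS["bone"]

    # bladder (anterior midline) and treatment target just posterior to it
    rbl = tuple(U(*r) for r in params.bladder_radii_mm)
    c_bl = (cz, cy - 0.42 * ry, cx + U(-0.05, 0.05) * rx)
    bladder = _ellipsoid(z, y, x, c_bl, rbl) & inner & (cmap != CLASS_LABELS["bone"])
    cmap[bladder] = CLASS_LABELS["bladder"]
    c_tg = (cz, c_bl[1] + rbl[1] + 0.6 * params.target_radii_mm[1], c_bl[2])
    target = _ellipsoid(z, y, x, c_tg, params.target_radii_mm) & inner

    # gas pockets in the bowel region (soft tissue only)
    n_gas = int(rng.integers(params.n_gas_range[0], params.n_gas_range[1] + 1))
    soft = CLASS_LABELS["soft_tissue"]
    for _ in range(n_gas):
        rg = U(*params.gas_radius_mm)
        c = (cz + U(-0.3, 0.3) * nz * dz / 2,
             cy - U(0.0, 0.25) * ry,
             cx + U(-0.45, 0.45) * rx)
        pocket = _ellipsoid(z, y, x, c, (rg, rg, rg))
        cmap[pocket & (cmap == soft) & ~target] = CLASS_LABELS["gas"]

    body_mask = cmap != CLASS_LABELS["air"]
    labels, n_comp = ndimage.label(body_mask)
    if n_comp != 1:
        # keep the largest component (possible only for extreme geometry draws)
        sizes = ndimage.sum_labels(body_mask, labels, range(1, n_comp + 1))
        body_mask = labels == (1 + int(np.argmax(sizes)))
        cmap[~body_mask] = CLASS_LABELS["air"]

    def render(mean: dict, sd: dict, noise: np.ndarray) -> np.ndarray:
        mean_lut = np.array([mean[CLASS_NAMES[i]] for i in range(len(CLASS_LABELS))])
        sd_lut = np.array([sd[CLASS_NAMES[i]] for i in range(len(CLASS_LABELS))])
        return (mean_lut[cmap] + sd_lut[cmap] * noise).astype(np.float32)

    def smooth_noise() -> np.ndarray:
        n = rng.standard_normal(shape)
        n = ndimage.gaussian_filter(n, sigma=params.noise_smooth_sigma)
        n /= max(n.std(), 1e-12)
        return np.clip(n, -4.0, 4.0)  # bounds every class to mean +/- 4 sd

    ct = render(params.hu_mean, params.hu_sd, smooth_noise())
    mr = render(params.mr_mean, params.mr_sd, smooth_noise())

    grid = dict(spacing=spacing, origin=(0.0, 0.0, 0.0))
    return PairedCase(
        mr=Volume(mr, modality="MR", **grid),
        ct=Volume(ct, modality="CT", **grid),
        body_mask=Volume(body_mask.astype(np.uint8), modality="MASK", **grid),
        class_map=cmap,
        seed=int(seed),
        target_mask=Volume(target.astype(np.uint8), modality="MASK", **grid),
        case_id=f"case{int(seed):06d}",
    )


def _bias_field(shape: tuple, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [-amplitude, amplitude], a sum of 2-3
    low-order cosine modes with random phases."""
    nz, ny, nx = shape
    z = np.linspace(0, 1, nz)[:, None, None]
    y = np.linspace(0, 1, ny)[None, :, None]
    x = np.linspace(0, 1, nx)[None, None, :]
    n_modes = int(rng.integers(2, 4))
    f = np.zeros(shape)
    for _ in range(n_modes):
        freq = rng.uniform(0.5, 1.5, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.uniform(0.5, 1.0)
        f += amp * (np.cos(2 * np.pi * freq[0] * z + phase[0])
                    * np.cos(2 * np.pi * freq[1] * y + phase[1])
                    * np.cos(2 * np.pi * freq[2] * x + phase[2]))
    peak = np.abs(f).max()
    return amplitude * f / max(peak, 1e-12)


def apply_scan_variation(mr: Volume, gain: float, offset: float,
                         bias_amplitude: float, noise_sd: float,
                         seed: int) -> Volume:
    """Simulate inter-scan MR intensity drift on an existing volume.

    Applies ``gain * mr * (1 + bias) + offset + noise`` where ``bias`` is a
    smooth low-frequency field with peak amplitude ``bias_amplitude``.  With
    identity parameters (gain 1, offset 0, no bias, no noise) the output is
    bit-identical to the input.
    """
    if mr.modality != "MR":
        raise ValueError(f"scan variation applies to MR volumes, got {mr.modality}")
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    rng = np.random.default_rng(seed)
    out = mr.data.astype(np.float32)
    if gain != 1.0:
        out = gain * out
    if bias_amplitude != 0.0:
        out = out * (1.0 + _bias_field(mr.shape, bias_amplitude, rng)).astype(np.float32)
    if offset != 0.0:
        out = out + np.float32(offset)
    if noise_sd != 0.0:
        out = out + rng.normal(0.0, noise_sd, mr.shape).astype(np.float32)
    return mr.with_data(out.astype(np.float32))


def _case_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + 7_919 * i + 17) % (2 ** 31 - 1))


def generate_cohort(n_train: int = 40, n_test: int = 10, seed: int = 0,
                    variation: ScanVariation | None = None,
                    shape: tuple = (16, 64, 64),
                    spacing: tuple = (3.0, 2.0, 2.0),
                    params: TissueParams | None = None,
                    ) -> tuple[list[PairedCase], list[PairedCase]]:
    """Seeded cohort of paired phantoms with per-case MR acquisition drift.

    The defaults ``n_train=40, n_test=10`` mirror the study design of 50
    subject pairs split 40/10.  Every case gets a distinct derived seed;
    train and test are disjoint by construction.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must both be >= 1")
    variation = variation or ScanVariation()
    cases = []
    for i in range(n_train + n_test):
        cs = _case_seed(seed, i)
        case = generate_phantom(cs, shape=shape, spacing=spacing, params=params)
        vr = np.random.default_rng(cs + 1)
        mr = apply_scan_variation(
            case.mr,
            gain=vr.uniform(*variation.gain_range),
            offset=vr.uniform(*variation.offset_range),
            bias_amplitude=vr.uniform(*variation.bias_amplitude_range),
            noise_sd=vr.uniform(*variation.noise_sd_range),
            seed=cs + 2,
        )
        cases.append(replace(case, mr=mr))
    return cases[:n_train], cases[n_train:]
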