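"""Image- and dosimetry-similarity metrics plus the paired t-test.

Image similarity: MAE (HU) and windowed SSIM inside a region of
interest, Dice overlap for body contours.  Dosimetry similarity: the 3D
gamma index combining a dose-difference criterion (% of the prescription
under global normalization) with a distance-to-agreement criterion (mm),
and the gamma passing rate (GPR) over voxels above a dose cut-off.

The gamma search minimizes over a dense displacement lattice (pitch
``dta/10`` up to radius ``3*dta``) with trilinear interpolation of the
evaluated dose; displacements are visited in order of increasing
magnitude so a voxel drops out of the search as soon as no farther
displacement can lower its gamma (``|delta|/dta`` alone already exceeds
the running minimum).  This early-exit strategy is exactly equivalent to
the exhaustive minimum over the same lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage, stats

from .dose import DoseGrid
from .volume import Volume


# --------------------------------------------------------------------- #
# image similarity

@dataclass
class MetricParams:
    """SSIM constants and window (2D Gaussian-weighted, per axial slice)."""

    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_window: int = 7
    ssim_sigma: float = 1.5
    data_range: float = 2500.0  # default CT window width in HU

    def __post_init__(self):
        if self.ssim_k1 <= 0 or self.ssim_k2 <= 0:
            raise ValueError("SSIM constants k1, k2 must be > 0")
        if self.ssim_window % 2 == 0 or self.ssim_window < 3:
            raise ValueError("SSIM window must be odd and >= 3")
        if self.data_range <= 0:
            raise ValueError("data_range must be > 0")


def _roi(a: Volume, b: Volume, mask: Volume | None):
    a.check_same_grid(b, "metric inputs")
    if mask is None:
        m = np.ones(a.shape, dtype=bool)
    else:
        a.check_same_grid(mask, "metric input and mask")
        m = np.asarray(mask.data) > 0
        if not m.any():
            raise ValueError("metric mask is empty")
    return m


def mae(a: Volume, b: Volume, mask: Volume | None = None) -> float:
    """Mean absolute difference over the mask (HU for CT inputs)."""
    m = _roi(a, b, mask)
    return float(np.mean(np.abs(np.asarray(a.data, dtype=np.float64)
                                - np.asarray(b.data, dtype=np.float64))[m]))


def gaussian_kernel2d(size: int, sigma: float) -> np.ndarray:
    """Normalized 2D Gaussian window of odd ``size``."""
    r = np.arange(size) - size // 2
    g = np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(a: Volume, b: Volume, mask: Volume | None = None,
         params: MetricParams | None = None) -> float:
    """Mean structural similarity, computed per axial slice and averaged.

    Local statistics use a Gaussian-weighted window; the SSIM map is
    averaged over mask-covered voxels per slice, then over slices with
    any coverage.  Identical inputs give exactly 1.0.
    """
    p = params or MetricParams()
    m = _roi(a, b, mask)
    kern = gaussian_kernel2d(p.ssim_window, p.ssim_sigma)
    c1 = (p.ssim_k1 * p.data_range) ** 2
    c2 = (p.ssim_k2 * p.data_range) ** 2
    slice_means = []
    for z in range(a.shape[0]):
        mz = m[z]
        if not mz.any():
            continue  # slices without mask coverage are skipped
        x = np.asarray(a.data[z], dtype=np.float64)
        y = np.asarray(b.data[z], dtype=np.float64)
        # "reflect" repeats the edge sample (numpy's "symmetric" padding)
        f = lambda img: ndimage.correlate(img, kern, mode="reflect")
        mux, muy = f(x), f(y)
        sxx = f(x * x) - mux * mux
        syy = f(y * y) - muy * muy
        sxy = f(x * y) - mux * muy
        smap = ((2 * mux * muy + c1) * (2 * sxy + c2)) / (
            (mux * mux + muy * muy + c1) * (sxx + syy + c2))
        slice_means.append(smap[mz].mean())
    if not slice_means:
        raise ValueError("no slice has mask coverage")
    return float(np.mean(slice_means))


def dice(mask_a: Volume, mask_b: Volume) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    mask_a.check_same_grid(mask_b, "masks")
    a = np.asarray(mask_a.data)
    b = np.asarray(mask_b.data)
    for name, arr in (("mask_a", a), ("mask_b", b)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (values 0/1)")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


# --------------------------------------------------------------------- #
# gamma index / GPR

@dataclass
class GammaParams:
    """Gamma criteria: dose difference (% of prescription), DTA (mm),
    reference-dose cut-off, and the displacement-search lattice."""

    dose_diff_pct: float = 1.0
    dta_mm: float = 1.0
    cutoff_fraction: float = 0.10
    normalization: str = "global"  # "global" (to prescription) or "local"
    search_radius_mm: float | None = None  # default 3 * dta_mm
    search_step_mm: float | None = None  # default dta_mm / 10
    pass_threshold: float = 1.0
    interpolate: bool = True  # False: voxel-centre displacements only

    def __post_init__(self):
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0 or self.pass_threshold <= 0:
            raise ValueError("gamma criteria must be positive")
        if not 0 < self.cutoff_fraction < 1:
            raise ValueError("cutoff_fraction must lie in (0, 1)")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")
        if self.search_radius_mm is None:
            self.search_radius_mm = 3.0 * self.dta_mm
        if self.search_step_mm is None:
            self.search_step_mm = self.dta_mm / 10.0


@dataclass
class GammaMap:
    """Per-voxel gamma values (unclipped) on the evaluated region."""

    gamma: Volume
    evaluated_mask: np.ndarray
    params: GammaParams
    ref: DoseGrid | None = None


def _displacement_lattice(params: GammaParams,
                          spacing: tuple) -> np.ndarray:
    """All search displacements (mm, z/y/x) within the search sphere,
    sorted by increasing magnitude; includes the zero displacement."""
    r = params.search_radius_mm
    if params.interpolate:
        axes = []
        for _ in range(3):
            n = int(np.floor(r / params.search_step_mm))
            axes.append(np.arange(-n, n + 1) * params.search_step_mm)
    else:
        axes = [np.arange(-int(np.floor(r / s)), int(np.floor(r / s)) + 1) * s
                for s in spacing]
    dz, dy, dx = np.meshgrid(*axes, indexing="ij")
    disp = np.stack([dz.ravel(), dy.ravel(), dx.ravel()], axis=1)
    norms = np.linalg.norm(disp, axis=1)
    keep = norms <= r + 1e-9
    disp, norms = disp[keep], norms[keep]
    order = np.argsort(norms, kind="stable")
    return disp[order], norms[order]


@njit(cache=True, fastmath=True)  # all inputs finite; no NaN/inf semantics used
def _gamma_search(devl, vox_idx, refs, dd, disp_vox, rho):
    """Per-voxel minimum over distance-sorted displacements.

    ``disp_vox`` holds displacements in (fractional) voxel units, sorted
    by increasing physical magnitude; ``rho`` is the matching
    ``|delta| / dta``.  The inner loop breaks as soon as the distance
    term alone exceeds the running minimum, which cannot change the
    result because every remaining candidate is at least that large.
    Trilinear interpolation of the evaluated dose is inlined;
    displacements that leave the grid are skipped.
    """
    nz, ny, nx = devl.shape
    n_vox = vox_idx.shape[0]
    n_disp = disp_vox.shape[0]
    out = np.empty(n_vox)
    for v in range(n_vox):
        iz, iy, ix = vox_idx[v, 0], vox_idx[v, 1], vox_idx[v, 2]
        gmin2 = ((devl[iz, iy, ix] - refs[v]) / dd[v]) ** 2  # zero shift
        for k in range(1, n_disp):
            r = rho[k]
            if r * r >= gmin2:
                break
            cz = iz + disp_vox[k, 0]
            cy = iy + disp_vox[k, 1]
            cx = ix + disp_vox[k, 2]
            if (cz < -1e-9 or cz > nz - 1 + 1e-9
                    or cy < -1e-9 or cy > ny - 1 + 1e-9
                    or cx < -1e-9 or cx > nx - 1 + 1e-9):
                continue
            bz = min(max(int(np.floor(cz)), 0), nz - 2) if nz > 1 else 0
            by = min(max(int(np.floor(cy)), 0), ny - 2) if ny > 1 else 0
            bx = min(max(int(np.floor(cx)), 0), nx - 2) if nx > 1 else 0
            fz, fy, fx = cz - bz, cy - by, cx - bx
            v00 = devl[bz, by, bx] * (1 - fx) + devl[bz, by, bx + 1] * fx
            v01 = devl[bz, by + 1, bx] * (1 - fx) + devl[bz, by + 1, bx + 1] * fx
            v10 = devl[bz + 1, by, bx] * (1 - fx) + devl[bz + 1, by, bx + 1] * fx
            v11 = devl[bz + 1, by + 1, bx] * (1 - fx) + devl[bz + 1, by + 1, bx + 1] * fx
            val = ((v00 * (1 - fy) + v01 * fy) * (1 - fz)
                   + (v10 * (1 - fy) + v11 * fy) * fz)
            g2 = r * r + ((val - refs[v]) / dd[v]) ** 2
            if g2 < gmin2:
                gmin2 = g2
        out[v] = np.sqrt(gmin2)
    return out


def gamma_index(ref: DoseGrid, eval: DoseGrid,
                params: GammaParams | None = None) -> GammaMap:
    """3D gamma between a reference and an evaluated dose distribution.

    gamma(r) = min over displacements ``d`` (|d| <= search radius) of
    ``sqrt(|d|^2/dta^2 + (D_eval(r+d) - D_ref(r))^2 / dD^2)`` where ``dD``
    is ``dose_diff_pct%`` of the prescription (global normalization) and
    ``D_eval`` is trilinearly interpolated on the search lattice.  Only
    reference voxels at or above the dose cut-off are evaluated.
    """
    params = params or GammaParams()
    rvol, evol = ref.volume, eval.volume
    rvol.check_same_grid(evol, "reference and evaluated dose grids")
    dref = np.asarray(rvol.data, dtype=np.float64)
    devl = np.ascontiguousarray(evol.data, dtype=np.float64)
    cutoff = params.cutoff_fraction * ref.prescription_gy
    emask = dref >= cutoff
    if not emask.any():
        raise ValueError(
            f"dose cut-off {cutoff:.3g} Gy excludes every voxel")

    if params.normalization == "global":
        dd = np.full(int(emask.sum()), params.dose_diff_pct / 100.0
                     * ref.prescription_gy)
    else:
        dd = params.dose_diff_pct / 100.0 * dref[emask]

    idx = np.ascontiguousarray(np.argwhere(emask))
    refs = dref[emask]
    disp, norms = _displacement_lattice(params, rvol.spacing)
    disp_vox = np.ascontiguousarray(disp / np.asarray(rvol.spacing))
    rho = norms / params.dta_mm

    gmin = _gamma_search(devl, idx, refs, dd, disp_vox, rho)

    gamma = np.full(rvol.shape, np.nan)
    gamma[emask] = gmin
    gvol = Volume(gamma, rvol.spacing, rvol.origin, "DOSE")
    return GammaMap(gvol, emask, params, ref)


def gamma_passing_rate(gmap: GammaMap,
                       cutoff_fraction: float | None = None) -> float:
    """Percentage of evaluated voxels with gamma <= pass threshold.

    ``cutoff_fraction`` may raise the dose cut-off above the one the map
    was computed with, restricting the rate to a subset of the evaluated
    voxels (e.g. the high-dose region).
    """
    emask = gmap.evaluated_mask
    if cutoff_fraction is not None:
        if gmap.ref is None:
            raise ValueError("gamma map lacks its reference dose")
        if cutoff_fraction < gmap.params.cutoff_fraction:
            raise ValueError(
                "cutoff_fraction cannot go below the map's evaluated cut-off")
        dref = np.asarray(gmap.ref.volume.data, dtype=np.float64)
        emask = emask & (dref >= cutoff_fraction * gmap.ref.prescription_gy)
    n = int(emask.sum())
    if n == 0:
        raise ValueError("no voxels above the dose cut-off")
    g = np.asarray(gmap.gamma.data)[emask]
    return float(100.0 * np.count_nonzero(g <= gmap.params.pass_threshold) / n)


# --------------------------------------------------------------------- #
# statistics

@dataclass
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


def paired_t_test(x, y) -> TTestResult:
    """Two-sided paired-samples t-test on matched measurements.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with sample standard deviation
    (n-1 denominator) on the differences ``d = x - y``; the p-value comes
    from Student's t with ``n - 1`` degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; t-test undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p))
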