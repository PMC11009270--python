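"""Independent brute-force reference implementations used only by tests.

These are deliberately written with different algorithms from the
package code paths they check: the gamma oracle is an exhaustive
separable-interpolation minimum over the full displacement lattice (no
early exit, no sorted shells), and the SSIM oracle is a naive
sliding-window loop.
"""

from __future__ import annotations

import numpy as np


def _shift_interp(arr: np.ndarray, axis: int, offset_vox: float) -> np.ndarray:
    """Values of ``arr`` sampled at index + offset along ``axis`` with linear
    interpolation; positions outside the array become NaN."""
    def shifted(k: int) -> np.ndarray:
        out = np.full_like(arr, np.nan)
        n = arr.shape[axis]
        if -n < k < n:
            src = [slice(None)] * arr.ndim
            dst = [slice(None)] * arr.ndim
            if k >= 0:
                src[axis] = slice(k, n)
                dst[axis] = slice(0, n - k)
            else:
                src[axis] = slice(0, n + k)
                dst[axis] = slice(-k, n)
            out[tuple(dst)] = arr[tuple(src)]
        return out

    base = int(np.floor(offset_vox))
    frac = offset_vox - base
    if frac < 1e-12:
        return shifted(base)
    return (1.0 - frac) * shifted(base) + frac * shifted(base + 1)


def gamma_brute_force(ref_dose: np.ndarray, eval_dose: np.ndarray,
                      spacing, prescription: float,
                      dose_diff_pct: float = 1.0, dta_mm: float = 1.0,
                      cutoff_fraction: float = 0.10,
                      search_radius_mm: float | None = None,
                      search_step_mm: float | None = None) -> np.ndarray:
    """Exhaustive gamma over the full displacement lattice.

    Every product-lattice displacement within the search sphere is
    evaluated via separable linear interpolation of the evaluated dose
    (x-shifts precomputed once, y-shifts batched per z-shift) and the
    plain minimum is taken — no early exit.  Returns a full-volume array
    with NaN below the cut-off.
    """
    radius = 3.0 * dta_mm if search_radius_mm is None else search_radius_mm
    step = dta_mm / 10.0 if search_step_mm is None else search_step_mm
    dref = np.asarray(ref_dose, dtype=np.float64)
    devl = np.asarray(eval_dose, dtype=np.float64)
    spacing = np.asarray(spacing, dtype=np.float64)
    dd = dose_diff_pct / 100.0 * prescription
    inv_dd = 1.0 / dd
    emask = dref >= cutoff_fraction * prescription

    n_off = int(np.floor(radius / step))
    offsets = np.arange(-n_off, n_off + 1) * step  # mm, identical per axis
    n_o = len(offsets)
    nz, ny, nx = dref.shape

    def _shift_into(dst: np.ndarray, src: np.ndarray, axis: int,
                    offset_vox: float) -> None:
        """dst[i] = src interpolated at index i + offset along ``axis``;
        positions outside become +inf (excluded by the minimum, since the
        squared dose term keeps them at +inf)."""
        base = int(np.floor(offset_vox))
        frac = offset_vox - base
        n = src.shape[axis]
        dst[...] = np.inf

        def sl(lo, hi, shift=0):
            out = [slice(None)] * src.ndim
            out[axis] = slice(lo + shift, hi + shift)
            return tuple(out)

        if frac < 1e-12:
            lo, hi = max(0, -base), min(n, n - base)
            if lo < hi:
                dst[sl(lo, hi)] = src[sl(lo, hi, base)]
        else:
            # both neighbours must be in range: i+base and i+base+1
            lo, hi = max(0, -base), min(n, n - base - 1)
            if lo < hi:
                dst[sl(lo, hi)] = (1.0 - frac) * src[sl(lo, hi, base)]
                dst[sl(lo, hi)] += frac * src[sl(lo, hi, base + 1)]

    # all x-shifted copies, once, pre-scaled by 1/dd: (n_ox, z, y, x)
    xs = np.empty((n_o, nz, ny, nx))
    for i, ox in enumerate(offsets):
        _shift_into(xs[i], devl, 2, ox / spacing[2])
    xs *= inv_dd
    drefs = dref * inv_dd

    # squared-distance lookup per (oy, ox) pair, +oz^2 added in the loop
    d2_yx = offsets[:, None] ** 2 + offsets[None, :] ** 2  # (n_oy, n_ox)

    block = 12  # y-offsets per arithmetic pass (keeps the buffer cache-sized)
    sz = np.empty_like(xs)
    g = np.empty((block, n_o, nz, ny, nx))  # (oy-block, ox, z, y, x)
    gmin2 = np.full(dref.shape, np.inf)
    for oz in offsets:
        _shift_into(sz, xs, 1, oz / spacing[0])  # z-axis of the 4D stack
        norms = np.sqrt(d2_yx + oz * oz)
        rho2 = np.where(norms <= radius + 1e-9,
                        (d2_yx + oz * oz) / dta_mm ** 2, np.inf)
        for b0 in range(0, n_o, block):
            nb = min(block, n_o - b0)
            gb = g[:nb]
            for i in range(nb):
                _shift_into(gb[i], sz, 2, offsets[b0 + i] / spacing[1])
            gb -= drefs[None, None]
            np.square(gb, out=gb)
            gb += rho2[b0:b0 + nb, :, None, None, None]
            np.minimum(gmin2, gb.min(axis=(0, 1)), out=gmin2)
    gamma = np.sqrt(gmin2)
    gamma[~emask] = np.nan
    return gamma


def ssim_sliding_window(a: np.ndarray, b: np.ndarray, mask: np.ndarray,
                        kernel: np.ndarray, c1: float, c2: float) -> float:
    """Naive per-slice windowed SSIM: explicit loops over window positions
    with reflect padding, averaged over mask-covered voxels then slices."""
    half = kernel.shape[0] // 2
    slice_means = []
    for z in range(a.shape[0]):
        if not mask[z].any():
            continue
        x = np.pad(a[z].astype(np.float64), half, mode="symmetric")
        y = np.pad(b[z].astype(np.float64), half, mode="symmetric")
        vals = []
        for i, j in np.argwhere(mask[z]):
            wx = x[i:i + 2 * half + 1, j:j + 2 * half + 1]
            wy = y[i:i + 2 * half + 1, j:j + 2 * half + 1]
            mx = (kernel * wx).sum()
            my = (kernel * wy).sum()
            vx = (kernel * wx * wx).sum() - mx * mx
            vy = (kernel * wy * wy).sum() - my * my
            cov = (kernel * wx * wy).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * cov + c2))
                        / ((mx * mx + my * my + c1) * (vx + vy + c2)))
        slice_means.append(np.mean(vals))
    return float(np.mean(slice_means))
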