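"""Intensity standardization and grid harmonization.

Implements the piece-wise linear histogram-matching (Nyul) MR intensity
standardization: foreground landmarks at fixed percentiles are mapped
onto a learned standard scale, removing per-scan gain/offset/bias drift
while preserving intensity order.  CT volumes are deliberately not
standardized — their scale (HU) is already physical.

Also provides automatic body-contour extraction (Otsu threshold, largest
connected component, hole filling), rigid translation-only resampling
onto a reference grid, and the affine [-1, 1] window scaling used for
network input/output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

from .volume import Volume

DEFAULT_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)
DEFAULT_S_RANGE = (0.0, 100.0)

#: default intensity windows mapped onto [-1, 1] for network training
DEFAULT_CT_WINDOW = None  # set below once ScaleWindow exists


@dataclass
class ScaleWindow:
    """Intensity window ``[lo, hi]`` affinely mapped onto [-1, 1]."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got ({self.lo}, {self.hi})")


DEFAULT_CT_WINDOW = ScaleWindow(-1000.0, 1500.0)
DEFAULT_MR_WINDOW = ScaleWindow(0.0, 100.0)


@dataclass
class StandardScale:
    """Nyul landmark percentiles and the learned standard-scale values."""

    percentiles: tuple = DEFAULT_PERCENTILES
    standard_landmarks: tuple = ()
    s_range: tuple = DEFAULT_S_RANGE

    def __post_init__(self):
        p = np.asarray(self.percentiles, dtype=float)
        if p.ndim != 1 or len(p) < 2 or np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing, length >= 2")
        if np.any(p <= 0) or np.any(p >= 100):
            raise ValueError("percentiles must lie in the open interval (0, 100)")
        if len(self.standard_landmarks):
            lm = np.asarray(self.standard_landmarks, dtype=float)
            if len(lm) != len(p):
                raise ValueError("one standard landmark per percentile required")
            if np.any(np.diff(lm) <= 0):
                raise ValueError("standard landmarks must be strictly increasing")
            if not (np.isclose(lm[0], self.s_range[0])
                    and np.isclose(lm[-1], self.s_range[1])):
                raise ValueError("outermost standard landmarks must equal s_range")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "percentiles": list(self.percentiles),
            "standard_landmarks": list(self.standard_landmarks),
            "s_range": list(self.s_range),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardScale":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["percentiles"]), tuple(d["standard_landmarks"]),
                   tuple(d["s_range"]))


def _foreground(image: Volume, mask: Volume | None) -> np.ndarray:
    if mask is None:
        return np.asarray(image.data, dtype=np.float64).ravel()
    image.check_same_grid(mask, "image and mask")
    fg = np.asarray(image.data, dtype=np.float64)[np.asarray(mask.data) > 0]
    if fg.size == 0:
        raise ValueError("empty foreground: mask selects no voxels")
    return fg


def _landmarks(image: Volume, mask: Volume | None, percentiles,
               name: str = "image") -> np.ndarray:
    fg = _foreground(image, mask)
    lm = np.percentile(fg, percentiles)
    if np.any(np.diff(lm) <= 0):
        raise ValueError(
            f"{name}: non-increasing intensity landmarks (constant or "
            "near-constant foreground); cannot standardize"
        )
    return lm


def compute_standard_scale(images: list[Volume], masks: list[Volume] | None = None,
                           percentiles=DEFAULT_PERCENTILES,
                           s_range=DEFAULT_S_RANGE) -> StandardScale:
    """Learn the standard scale from a set of MR volumes.

    Per image, foreground landmarks at ``percentiles`` are linearly mapped
    so the outermost pair lands on ``s_range``; the mapped landmarks are
    then averaged across images.  This is invariant to per-image gain and
    offset, so two scans differing only affinely contribute identically.
    """
    if len(images) == 0:
        raise ValueError("at least one image is required")
    if masks is None:
        masks = [None] * len(images)
    if len(masks) != len(images):
        raise ValueError("need one mask per image")
    s_min, s_max = float(s_range[0]), float(s_range[1])
    if not s_min < s_max:
        raise ValueError("s_range must be increasing")
    mapped = []
    for i, (img, msk) in enumerate(zip(images, masks)):
        lm = _landmarks(img, msk, percentiles, name=f"image {i}")
        mapped.append(s_min + (lm - lm[0]) * (s_max - s_min) / (lm[-1] - lm[0]))
    std = np.mean(mapped, axis=0)
    std[0], std[-1] = s_min, s_max
    return StandardScale(tuple(percentiles), tuple(std), (s_min, s_max))


def nyul_transform(image: Volume, scale: StandardScale,
                   mask: Volume | None = None) -> Volume:
    """Map an MR volume onto the standard scale.

    The image's own foreground landmarks are sent exactly onto
    ``scale.standard_landmarks`` with piecewise-linear interpolation in
    between; beyond the outermost landmarks values continue linearly with
    the adjacent segment's slope.  The map is non-decreasing.
    """
    if not len(scale.standard_landmarks):
        raise ValueError("scale has no learned standard_landmarks; fit first")
    lm = _landmarks(image, mask, scale.percentiles)
    std = np.asarray(scale.standard_landmarks, dtype=np.float64)
    x = np.asarray(image.data, dtype=np.float64)
    out = np.interp(x, lm, std)
    lo_slope = (std[1] - std[0]) / (lm[1] - lm[0])
    hi_slope = (std[-1] - std[-2]) / (lm[-1] - lm[-2])
    below = x < lm[0]
    above = x > lm[-1]
    out[below] = std[0] + (x[below] - lm[0]) * lo_slope
    out[above] = std[-1] + (x[above] - lm[-1]) * hi_slope
    return image.with_data(out.astype(np.float32), modality="MR")


class NyulStandardizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping Nyul standardization.

    ``fit`` learns the standard scale from a list of MR volumes (with
    optional foreground masks); ``transform`` maps volumes onto it.

    Attributes
    ----------
    scale_ : StandardScale
        The learned landmark scale.
    """

    def __init__(self, percentiles=DEFAULT_PERCENTILES, s_range=DEFAULT_S_RANGE):
        self.percentiles = percentiles
        self.s_range = s_range

    def fit(self, X: list[Volume], y=None, masks: list[Volume] | None = None):
        self.scale_ = compute_standard_scale(X, masks, self.percentiles, self.s_range)
        return self

    def transform(self, X, masks=None):
        if isinstance(X, Volume):
            return nyul_transform(X, self.scale_, masks)
        if masks is None:
            masks = [None] * len(X)
        return [nyul_transform(img, self.scale_, m) for img, m in zip(X, masks)]


def extract_body_mask(volume: Volume) -> Volume:
    """Automatic body contour: Otsu threshold, largest connected component,
    hole filling slice-wise and in 3D."""
    data = np.asarray(volume.data, dtype=np.float64)
    if np.ptp(data) == 0:
        raise ValueError("cannot extract a body mask from a constant volume")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise ValueError("empty mask after Otsu thresholding")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, range(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    for k in range(fg.shape[0]):
        fg[k] = ndimage.binary_fill_holes(fg[k])
    fg = ndimage.binary_fill_holes(fg)
    return volume.with_data(fg.astype(np.uint8), modality="MASK")


def _background_value(volume: Volume) -> float:
    d = volume.data
    border = np.concatenate([d[0].ravel(), d[-1].ravel(), d[:, 0].ravel(),
                             d[:, -1].ravel(), d[:, :, 0].ravel(),
                             d[:, :, -1].ravel()])
    return float(np.median(border))


def _resample_translated(moving: Volume, fixed: Volume, shift_mm) -> np.ndarray:
    """Sample ``moving`` at the fixed grid's world points minus ``shift``."""
    coords = []
    for a, w in enumerate(fixed.world_coordinates()):
        c = (w - shift_mm[a] - moving.origin[a]) / moving.spacing[a]
        snap = np.round(c)
        c = np.where(np.abs(c - snap) < 1e-9, snap, c)
        coords.append(c)
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(
        np.asarray(moving.data, dtype=np.float64), [zz, yy, xx],
        order=1, mode="constant", cval=_background_value(moving))


def _check_overlap(moving: Volume, fixed: Volume, shift_mm) -> None:
    for a in range(3):
        m_lo = moving.origin[a] + shift_mm[a]
        m_hi = m_lo + (moving.shape[a] - 1) * moving.spacing[a]
        f_lo = fixed.origin[a]
        f_hi = f_lo + (fixed.shape[a] - 1) * fixed.spacing[a]
        if m_hi < f_lo or f_hi < m_lo:
            raise ValueError(
                f"fields of view do not overlap along axis {a} "
                f"(moving [{m_lo}, {m_hi}] mm vs fixed [{f_lo}, {f_hi}] mm)"
            )


def _isotropic_refine(vol: Volume, step_mm: float = 1.0) -> Volume:
    """Cubic resample onto a ~``step_mm`` isotropic grid covering the same
    field of view (used so correlation is evaluated at fine scale, where
    interpolation blur no longer biases the optimum on coarse axes)."""
    sp = np.asarray(vol.spacing)
    shape = np.asarray(vol.shape)
    n_new = np.maximum(2, np.ceil((shape - 1) * sp / step_mm).astype(int) + 1)
    coords = np.meshgrid(
        *[np.linspace(0, shape[a] - 1, n_new[a]) for a in range(3)],
        indexing="ij")
    data = ndimage.map_coordinates(np.asarray(vol.data, dtype=np.float64),
                                   coords, order=3, mode="nearest")
    new_sp = (shape - 1) * sp / np.maximum(n_new - 1, 1)
    return Volume(data, tuple(new_sp), vol.origin, vol.modality)


def estimate_rigid_shift(moving: Volume, fixed: Volume,
                         search_mm: float = 5.0, step_mm: float = 1.0
                         ) -> tuple[float, float, float]:
    """Translation (mm, z/y/x) aligning ``moving`` to ``fixed``.

    Both volumes are first resampled to a ~1 mm isotropic grid.  Centre-of-
    mass alignment of the two body masks gives the initial guess; a local
    exhaustive search (+/- ``search_mm`` in ``step_mm`` steps per axis)
    then maximizes normalized cross-correlation of the intensities over
    the fixed body mask.
    """
    mov = _isotropic_refine(moving)
    fix = _isotropic_refine(fixed)
    m_mask = extract_body_mask(mov).data.astype(bool)
    f_mask = extract_body_mask(fix).data.astype(bool)

    def com_mm(mask, vol):
        idx = np.asarray(ndimage.center_of_mass(mask))
        return np.asarray(vol.origin) + idx * np.asarray(vol.spacing)

    shift0 = com_mm(f_mask, fix) - com_mm(m_mask, mov)
    _check_overlap(moving, fixed, shift0)

    # evaluate NCC on a strided subsample of the fixed body mask
    idx = np.argwhere(f_mask)
    if len(idx) > 16000:
        idx = idx[:: int(np.ceil(len(idx) / 16000))]
    world = np.asarray(fix.origin) + idx * np.asarray(fix.spacing)
    fvals = np.asarray(fix.data)[tuple(idx.T)]
    fvals = fvals - fvals.mean()
    fnorm = np.linalg.norm(fvals)
    mdata = np.asarray(mov.data)
    bg = _background_value(mov)
    offsets = np.arange(-search_mm, search_mm + step_mm / 2, step_mm)
    best, best_ncc = tuple(shift0), -np.inf
    for oz in offsets:
        for oy in offsets:
            for ox in offsets:
                s = shift0 + np.array([oz, oy, ox])
                coords = (world - s - np.asarray(mov.origin)) / np.asarray(mov.spacing)
                r = ndimage.map_coordinates(mdata, coords.T, order=1,
                                            mode="constant", cval=bg)
                r = r - r.mean()
                denom = np.linalg.norm(r) * fnorm
                ncc = float(r @ fvals / denom) if denom > 0 else -np.inf
                if ncc > best_ncc:
                    best_ncc, best = ncc, tuple(s)
    return tuple(float(v) for v in best)


def rigid_resample(moving: Volume, fixed: Volume,
                   shift: tuple | None = None) -> Volume:
    """Translate ``moving`` by ``shift`` (mm) and trilinearly resample it
    onto ``fixed``'s grid; out-of-field voxels take the moving volume's
    background value.  With ``shift=None`` the translation is estimated by
    :func:`estimate_rigid_shift`."""
    if shift is None:
        shift = estimate_rigid_shift(moving, fixed)
    _check_overlap(moving, fixed, shift)
    out = _resample_translated(moving, fixed, shift)
    return Volume(out.astype(np.float32), fixed.spacing, fixed.origin,
                  moving.modality)


def scale_to_unit(volume: Volume, window: ScaleWindow) -> Volume:
    """Affine map of ``[window.lo, window.hi]`` onto [-1, 1], clipped."""
    x = np.asarray(volume.data, dtype=np.float64)
    y = -1.0 + 2.0 * (x - window.lo) / (window.hi - window.lo)
    return volume.with_data(np.clip(y, -1.0, 1.0).astype(np.float32))


def unscale_from_unit(volume: Volume, window: ScaleWindow) -> Volume:
    """Exact inverse of :func:`scale_to_unit` on [-1, 1]."""
    y = np.asarray(volume.data, dtype=np.float64)
    x = window.lo + (y + 1.0) * (window.hi - window.lo) / 2.0
    return volume.with_data(x.astype(np.float32))
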