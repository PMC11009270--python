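"""Regular-grid 3D volumes with physical voxel spacing.

Arrays are indexed ``(z, y, x)`` with axial slices along ``z``; spacing and
origin are stored in millimetres in the same axis order.  The world
coordinate of voxel ``(i, j, k)`` is ``origin + (i*dz, j*dy, k*dx)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("MR", "CT", "DOSE", "MASK")


@dataclass
class Volume:
    """A 3D scalar grid plus geometry metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values: MR intensity (a.u.), CT Hounsfield units, dose in Gy,
        or a binary mask.
    spacing : tuple of float
        Voxel size ``(dz, dy, dx)`` in mm; all components positive.
    origin : tuple of float
        World coordinate of voxel ``(0, 0, 0)`` in mm.
    modality : str
        One of ``MR``, ``CT``, ``DOSE``, ``MASK``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "MR"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    # ------------------------------------------------------------------ #
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        """True when shape, spacing and origin all match within ``atol``."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def check_same_grid(self, other: "Volume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"{what} must share a grid: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "Volume":
        """New volume on this grid with different voxel values."""
        return replace(self, data=data, modality=modality or self.modality)

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world-coordinate vectors (mm) of voxel centres."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    # NIfTI I/O ---------------------------------------------------------- #
    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI; axes are stored (x, y, z) per the format."""
        dz, dy, dx = self.spacing
        z0, y0, x0 = self.origin
        affine = np.diag([dx, dy, dz, 1.0])
        affine[:3, 3] = (x0, y0, z0)
        arr = np.asarray(self.data).transpose(2, 1, 0)
        if self.modality == "MASK":
            arr = arr.astype(np.uint8)
        else:
            arr = arr.astype(np.float32)
        nib.save(nib.Nifti1Image(arr, affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str = "MR") -> "Volume":
        img = nib.load(str(path))
        affine = img.affine
        arr = np.asanyarray(img.dataobj).transpose(2, 1, 0)
        spacing = (abs(affine[2, 2]), abs(affine[1, 1]), abs(affine[0, 0]))
        origin = (affine[2, 3], affine[1, 3], affine[0, 3])
        return cls(arr, spacing, origin, modality)


@dataclass
class PairedCase:
    """One subject's aligned MR/CT pair with body mask and tissue labels.

    ``class_map`` holds integer tissue labels on the shared grid; ``mr`` and
    ``ct`` are generated from the same label field, so the pair is perfectly
    aligned by construction.  ``target_mask`` marks the treatment-target
    ellipsoid used by the dose engine.
    """

    mr: Volume
    ct: Volume
    body_mask: Volume
    class_map: np.ndarray
    seed: int
    target_mask: Volume | None = None
    case_id: str = ""

    def __post_init__(self) -> None:
        for name in ("ct", "body_mask"):
            self.mr.check_same_grid(getattr(self, name), f"mr and {name}")
        if self.class_map.shape != self.mr.shape:
            raise ValueError("class_map must share the paired grid")

    def save(self, outdir: str | Path, stem: str | None = None) -> None:
        """Write the case as NIfTI files plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = stem or (self.case_id or f"case{self.seed}")
        self.mr.to_nifti(outdir / f"{stem}_mr.nii.gz")
        self.ct.to_nifti(outdir / f"{stem}_ct.nii.gz")
        self.body_mask.to_nifti(outdir / f"{stem}_body.nii.gz")
        classes = self.body_mask.with_data(self.class_map.astype(np.int16), "MASK")
        classes.to_nifti(outdir / f"{stem}_classes.nii.gz")
        sidecar = {
            "seed": int(self.seed),
            "case_id": stem,
            "spacing_mm": list(self.mr.spacing),
            "origin_mm": list(self.mr.origin),
            "shape": list(self.mr.shape),
        }
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
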