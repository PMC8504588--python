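"""Regular-grid image volumes, dose grids, and structure sets.

Coordinate convention
---------------------
All world coordinates are patient coordinates in millimetres with the
origin at the pelvis reference mark: ``x`` increases toward the patient's
left, ``y`` anterior, ``z`` superior (toward the head).  Arrays are indexed
``values[ix, iy, iz]`` so that the world position of a voxel centre is
``origin + index * spacing``.

A head-first supine (HFS) volume stores voxels in ascending patient
coordinates.  A feet-first supine (FFS) volume stores the scanner's view of
a patient rotated 180 degrees about the vertical (y) axis: the stored x and
z axes run opposite to the patient axes.  :meth:`ImageVolume.in_patient_frame`
converts between the two; the conversion is an exact axis flip (no
interpolation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["Grid", "ImageVolume", "DoseGrid", "StructureSet"]

AIR_HU = -1000.0


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular 3-D raster: origin/spacing in mm, voxel counts."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")

    @classmethod
    def covering(
        cls,
        lo: tuple[float, float, float],
        hi: tuple[float, float, float],
        spacing: tuple[float, float, float],
    ) -> "Grid":
        """Smallest grid whose voxel extent covers the box [lo, hi]."""
        origin, shape = [], []
        for a, b, s in zip(lo, hi, spacing):
            n = max(1, int(np.ceil((b - a) / s)))
            origin.append(a + s / 2.0)
            shape.append(n)
        return cls(tuple(origin), tuple(spacing), tuple(shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (voxel edges, not centres)."""
        o = np.asarray(self.origin)
        s = np.asarray(self.spacing)
        n = np.asarray(self.shape)
        return o - s / 2.0, o + (n - 0.5) * s

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (N, 3)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def flipped_xz(self, center: tuple[float, float] = (0.0, 0.0)) -> "Grid":
        """Grid after a 180-degree rotation about the vertical axis through
        ``center = (x, z)``; voxel centres map exactly onto voxel centres."""
        cx, cz = center
        ox = 2.0 * cx - (self.origin[0] + (self.shape[0] - 1) * self.spacing[0])
        oz = 2.0 * cz - (self.origin[2] + (self.shape[2] - 1) * self.spacing[2])
        return Grid((ox, self.origin[1], oz), self.spacing, self.shape)

    def same_geometry(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class ImageVolume:
    """A CT-like or label raster on a :class:`Grid`.

    ``orientation`` is ``"HFS"`` or ``"FFS"`` (see module docstring).
    """

    grid: Grid
    values: np.ndarray
    orientation: str = "HFS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.orientation not in ("HFS", "FFS"):
            raise ValueError(f"orientation must be 'HFS' or 'FFS', got {self.orientation!r}")

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def in_patient_frame(self, center: tuple[float, float] = (0.0, 0.0)) -> "ImageVolume":
        """Return an HFS-ordered copy (exact flip for FFS input)."""
        if self.orientation == "HFS":
            return self
        return ImageVolume(
            self.grid.flipped_xz(center), self.values[::-1, :, ::-1].copy(), "HFS"
        )

    def to_ffs(self, center: tuple[float, float] = (0.0, 0.0)) -> "ImageVolume":
        if self.orientation == "FFS":
            return self
        return ImageVolume(
            self.grid.flipped_xz(center), self.values[::-1, :, ::-1].copy(), "FFS"
        )

    def sample(self, points: np.ndarray, order: int = 1, cval: float = AIR_HU) -> np.ndarray:
        """Interpolate at world points (N, 3); outside the grid -> ``cval``."""
        idx = self.grid.world_to_index(points).T
        return ndimage.map_coordinates(
            self.values.astype(np.float32, copy=False),
            idx,
            order=order,
            mode="constant",
            cval=cval,
            prefilter=False,
        )

    def crop_z(self, z_lo: float, z_hi: float) -> "ImageVolume":
        """Crop to slices whose centres lie in [z_lo, z_hi] (patient mm)."""
        zc = self.grid.axis_coords(2)
        keep = np.nonzero((zc >= z_lo) & (zc <= z_hi))[0]
        if keep.size == 0:
            raise ValueError(f"crop interval [{z_lo}, {z_hi}] contains no slices")
        i0, i1 = int(keep[0]), int(keep[-1]) + 1
        g = Grid(
            (self.origin[0], self.origin[1], float(zc[i0])),
            self.spacing,
            (self.shape[0], self.shape[1], i1 - i0),
        )
        return ImageVolume(g, self.values[:, :, i0:i1].copy(), self.orientation)

    def save(self, path: str | Path) -> None:
        """Write as NIfTI-1; the affine maps index -> patient mm as stored.

        The orientation flag is kept in the header ``descrip`` field.
        """
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        img.header["descrip"] = f"tbiplan:{self.orientation}".encode()
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(affine[i, i]) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        data = np.asarray(img.dataobj, dtype=np.float32)
        descrip = bytes(img.header["descrip"]).decode(errors="ignore")
        orientation = "FFS" if "FFS" in descrip else "HFS"
        return cls(Grid(origin, spacing, data.shape), data, orientation)


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a regular grid; additive under beam composition."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("dose values shape does not match grid")

    @classmethod
    def zeros(cls, grid: Grid) -> "DoseGrid":
        return cls(grid, np.zeros(grid.shape, dtype=np.float64))

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.grid, self.values.copy())

    def __add__(self, other: "DoseGrid") -> "DoseGrid":
        if not self.grid.same_geometry(other.grid):
            raise ValueError("cannot add dose grids with different geometry")
        return DoseGrid(self.grid, self.values + other.values)

    def __mul__(self, k: float) -> "DoseGrid":
        return DoseGrid(self.grid, self.values * float(k))

    __rmul__ = __mul__

    def column(self, x: float, y: float) -> tuple[np.ndarray, np.ndarray]:
        """Dose along the longitudinal line through (x, y): (z_mm, Gy)."""
        ix = int(round((x - self.grid.origin[0]) / self.grid.spacing[0]))
        iy = int(round((y - self.grid.origin[1]) / self.grid.spacing[1]))
        ix = int(np.clip(ix, 0, self.grid.shape[0] - 1))
        iy = int(np.clip(iy, 0, self.grid.shape[1] - 1))
        return self.grid.axis_coords(2), np.asarray(self.values[ix, iy, :], dtype=float)

    def shifted(self, displacement: tuple[float, float, float]) -> "DoseGrid":
        """Dose cloud rigidly translated by ``displacement`` (mm), linear
        interpolation; dose moves with the displacement (+dz moves dose
        superiorly)."""
        dv = [d / s for d, s in zip(displacement, self.grid.spacing)]
        if all(abs(d) < 1e-12 for d in dv):
            return self.copy()
        out = ndimage.shift(
            self.values, dv, order=1, mode="constant", cval=0.0, prefilter=False
        )
        return DoseGrid(self.grid, out)

    def flipped_xz(self, center: tuple[float, float] = (0.0, 0.0)) -> "DoseGrid":
        return DoseGrid(self.grid.flipped_xz(center), self.values[::-1, :, ::-1].copy())

    def save(self, path: str | Path) -> None:
        ImageVolume(self.grid, self.values).save(path)

    @classmethod
    def load(cls, path: str | Path) -> "DoseGrid":
        v = ImageVolume.load(path)
        return cls(v.grid, v.values)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid, plus longitudinal landmarks.

    ``masks`` holds at least ``body``; organ masks (``lungs``, ``kidneys``)
    must be subsets of the body.  ``landmarks`` maps names
    (``head_top``, ``neck_bottom``, ``legs_top``, ``feet_bottom``) to
    patient-frame z in mm.
    """

    grid: Grid
    masks: dict[str, np.ndarray]
    landmarks: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != tuple(self.grid.shape):
                raise ValueError(f"mask {name!r} shape {m.shape} != grid {self.grid.shape}")
            self.masks[name] = m

    def require(self, *names: str) -> None:
        for n in names:
            if n not in self.masks:
                raise ValueError(f"structure set is missing required mask {n!r}")

    def validate(self) -> None:
        self.require("body")
        body = self.masks["body"]
        for name, m in self.masks.items():
            if name != "body" and np.any(m & ~body):
                raise ValueError(f"mask {name!r} is not contained in the body")

    def mask_z_extent(self, name: str) -> tuple[float, float]:
        """Outer z extent (voxel edges) of a mask, mm."""
        m = self.masks[name]
        zs = np.nonzero(m.any(axis=(0, 1)))[0]
        if zs.size == 0:
            raise ValueError(f"mask {name!r} is empty")
        zc = self.grid.axis_coords(2)
        h = self.grid.spacing[2] / 2.0
        return float(zc[zs[0]] - h), float(zc[zs[-1]] + h)

    def save(self, directory: str | Path, stem: str = "structures") -> Path:
        """Write masks as NIfTI files plus a JSON sidecar with landmarks."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sidecar: dict = {"landmarks": self.landmarks, "masks": {}}
        for name, m in self.masks.items():
            p = directory / f"{stem}_{name}.nii.gz"
            ImageVolume(self.grid, m.astype(np.uint8)).save(p)
            sidecar["masks"][name] = p.name
        out = directory / f"{stem}.json"
        out.write_text(json.dumps(sidecar, indent=2))
        return out

    @classmethod
    def load(cls, sidecar_path: str | Path) -> "StructureSet":
        sidecar_path = Path(sidecar_path)
        meta = json.loads(sidecar_path.read_text())
        masks: dict[str, np.ndarray] = {}
        grid = None
        for name, fname in meta["masks"].items():
            v = ImageVolume.load(sidecar_path.parent / fname)
            grid = v.grid
            masks[name] = v.values > 0.5
        if grid is None:
            raise ValueError("structure sidecar lists no masks")
        return cls(grid, masks, {k: float(v) for k, v in meta["landmarks"].items()})


def resample_to_grid(
    volume: ImageVolume, grid: Grid, order: int = 1, cval: float = AIR_HU
) -> ImageVolume:
    """Resample a volume onto another grid (same patient frame)."""
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    ix = (xs - volume.origin[0]) / volume.spacing[0]
    iy = (ys - volume.origin[1]) / volume.spacing[1]
    iz = (zs - volume.origin[2]) / volume.spacing[2]
    coords = np.meshgrid(ix, iy, iz, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=np.float64),
        np.stack([c.ravel() for c in coords]),
        order=order,
        mode="constant",
        cval=cval,
        prefilter=False,
    ).reshape(grid.shape)
    return ImageVolume(grid, out, "HFS")
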