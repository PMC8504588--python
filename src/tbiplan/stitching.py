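"""Rigid registration of the feet-first scan to the head-first scan in the
pelvis overlap, and whole-body volume assembly.

Both scans are same-modality CT by construction, so the similarity metric
is the mean squared intensity difference.  The default mode solves a pure
translation (couch/vacuum-bag setup differences between the two
acquisitions are primarily translational); small rotations about the
patient axes are available as an option.  The optimization is a
deterministic coarse grid search followed by Powell refinement restricted
to the pelvis crop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .volumes import AIR_HU, Grid, ImageVolume

__all__ = ["RigidTransform", "register_pelvis", "stitch"]


@dataclass(frozen=True)
class RigidTransform:
    """Maps the feet-first scan into the head-first frame:
    ``aligned(p) = moving(R (p - c) + c + t)`` with pivot ``c`` at the
    pelvis mark.  Rotations are small fine corrections (<= 10 degrees)."""

    translation: tuple[float, float, float]  # mm
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pivot: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(abs(r) > 10.0 for r in self.rotation_deg):
            raise ValueError("rotations above 10 degrees are not a fine correction")

    @property
    def is_translation_only(self) -> bool:
        return all(abs(r) < 1e-12 for r in self.rotation_deg)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = np.radians(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Sample positions in the moving image for fixed-frame points."""
        p = np.atleast_2d(points)
        t = np.asarray(self.translation)
        if self.is_translation_only:
            return p + t
        c = np.asarray(self.pivot)
        return (p - c) @ self.matrix().T + c + t

    def inverse_map_points(self, points: np.ndarray) -> np.ndarray:
        """Sample positions in the fixed frame for moving-image points."""
        p = np.atleast_2d(points)
        t = np.asarray(self.translation)
        if self.is_translation_only:
            return p - t
        c = np.asarray(self.pivot)
        return (p - c - t) @ self.matrix() + c

    def to_dict(self) -> dict:
        return {
            "translation_mm": list(self.translation),
            "rotation_deg": list(self.rotation_deg),
            "pivot_mm": list(self.pivot),
        }


def _fixed_points(volume: ImageVolume, z_lo: float, z_hi: float, stride: int) -> tuple[np.ndarray, np.ndarray]:
    crop = volume.crop_z(z_lo, z_hi)
    g = crop.grid
    xs = g.axis_coords(0)[::stride]
    ys = g.axis_coords(1)[::stride]
    zs = g.axis_coords(2)
    pts = np.stack([c.ravel() for c in np.meshgrid(xs, ys, zs, indexing="ij")], axis=1)
    vals = crop.values[::stride, ::stride, :].ravel().astype(np.float32)
    return pts, vals


def register_pelvis(
    shf: ImageVolume,
    sff: ImageVolume,
    region: tuple[float, float],
    mode: str = "translation",
    coarse_range_mm: float = 12.0,
    coarse_step_mm: float = 3.0,
) -> RigidTransform:
    """Recover the rigid transform aligning the SFF scan to the SHF scan
    by minimizing the mean squared difference in the pelvis z-interval
    ``region`` (mm, patient frame)."""
    if mode not in ("translation", "rigid"):
        raise ValueError("mode must be 'translation' or 'rigid'")
    z_lo, z_hi = region
    if z_hi <= z_lo:
        raise ValueError("empty registration region")
    moving = sff.in_patient_frame()
    for vol, name in ((shf, "SHF"), (moving, "SFF")):
        lo, hi = vol.grid.extent
        if z_hi < lo[2] or z_lo > hi[2]:
            raise ValueError(f"registration region does not overlap the {name} scan")

    # The SFF voxels act as the fixed samples and the SHF scan is the
    # image interpolated during optimization; with the transform t mapping
    # SFF into the SHF frame, sff(r) should match shf(r - t).
    pts_c, vals_c = _fixed_points(moving, z_lo, z_hi, stride=4)
    pts_f, vals_f = _fixed_points(moving, z_lo, z_hi, stride=2)

    def metric(params: np.ndarray, pts: np.ndarray, vals: np.ndarray) -> float:
        if mode == "translation":
            t = RigidTransform(tuple(params))
        else:
            t = RigidTransform(tuple(params[:3]), tuple(params[3:]))
        mv = shf.sample(t.inverse_map_points(pts), cval=AIR_HU)
        return float(np.mean((mv - vals) ** 2))

    # deterministic coarse search over translations
    steps = np.arange(-coarse_range_mm, coarse_range_mm + 1e-9, coarse_step_mm)
    best, best_m = np.zeros(3), np.inf
    for tx in steps:
        for ty in steps:
            for tz in steps:
                m = metric(np.array([tx, ty, tz]), pts_c, vals_c)
                if m < best_m:
                    best_m, best = m, np.array([tx, ty, tz])

    x0 = best if mode == "translation" else np.concatenate([best, np.zeros(3)])
    res = optimize.minimize(
        metric,
        x0,
        args=(pts_f, vals_f),
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-9, "maxiter": 200},
    )
    if not res.success:
        raise RuntimeError(
            f"registration did not converge (final metric {res.fun:.4g}): {res.message}"
        )
    if mode == "translation":
        return RigidTransform(tuple(float(v) for v in res.x))
    return RigidTransform(tuple(float(v) for v in res.x[:3]),
                          tuple(float(v) for v in res.x[3:]))


def stitch(shf: ImageVolume, sff: ImageVolume, t: RigidTransform) -> ImageVolume:
    """Assemble the whole-body volume in the SHF patient frame.

    Slices above the mid-overlap plane are copied verbatim from the SHF
    scan (hard transition, SHF precedence); slices below come from the SFF
    scan resampled through ``t``.  The output grid extends the SHF grid
    inferiorly at the SHF spacing."""
    moving = sff.in_patient_frame()
    sz = shf.spacing[2]
    mlo, mhi = moving.grid.extent
    # content extent of the aligned SFF: aligned(p) = moving(p + t)
    aligned_top = mhi[2] - t.translation[2]
    aligned_bottom = mlo[2] - t.translation[2]
    shf_lo, shf_hi = shf.grid.extent
    if aligned_top < shf_lo[2] - 1e-9:
        raise ValueError(
            f"longitudinal gap of {shf_lo[2] - aligned_top:.1f} mm between scans"
        )

    n_below = max(0, int(np.ceil((shf.origin[2] - (aligned_bottom + sz / 2.0)) / sz)))
    out_grid = Grid(
        (shf.origin[0], shf.origin[1], shf.origin[2] - n_below * sz),
        shf.spacing,
        (shf.shape[0], shf.shape[1], shf.shape[2] + n_below),
    )
    values = np.full(out_grid.shape, AIR_HU, dtype=np.float32)

    z_mid = 0.5 * (shf_lo[2] + min(aligned_top, shf_hi[2]))
    zc = out_grid.axis_coords(2)
    from_shf = zc >= z_mid
    # verbatim SHF copy (identical grids above the transition)
    values[:, :, from_shf] = shf.values[:, :, from_shf[n_below:] if n_below else from_shf]

    below = np.nonzero(~from_shf)[0]
    if below.size:
        xs = out_grid.axis_coords(0)
        ys = out_grid.axis_coords(1)
        pts = np.stack(
            [c.ravel() for c in np.meshgrid(xs, ys, zc[below], indexing="ij")], axis=1
        )
        vals = moving.sample(t.map_points(pts), cval=AIR_HU)
        values[:, :, below] = vals.reshape(
            (out_grid.shape[0], out_grid.shape[1], below.size)
        ).astype(np.float32)
    return ImageVolume(out_grid, values, "HFS")
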