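"""Synthetic whole-body phantoms and paired head-first / feet-first scans.

The phantom is a stack of simple analytic solids — an ellipsoidal head on a
neck cylinder, an elliptic-cylinder trunk, and paired leg cylinders — with
embedded lung and kidney ellipsoids.  Realistic CT texture is a non-goal:
the downstream planning rules only need correct topology and dimensions.
Soft tissue is 0 HU, lungs -700 HU, air -1000 HU; the dose engine applies a
lung density override, so bone is omitted.

The pelvis reference mark is the world origin (0, 0, 0); z increases toward
the head.  By default it sits at 52% of the patient's height above the
soles, a standard anthropometric ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import AIR_HU, Grid, ImageVolume, StructureSet

__all__ = ["PhantomSpec", "generate_phantom", "split_scans"]

# Fraction of height from the soles to the pelvis reference mark.
PELVIS_FRACTION = 0.52
LUNG_HU = -700.0
BODY_HU = 0.0


def _cm(v: float) -> float:
    return v * 10.0


@dataclass(frozen=True)
class PhantomSpec:
    """Dimensions of a synthetic patient (cm unless noted).

    z coordinates are patient-frame cm relative to the pelvis mark.
    """

    height: float
    shoulder_width: float
    umbilicus_separation: float  # AP thickness at the umbilicus
    leg_width: float  # total width of both legs
    lung_center_z: float
    lung_length: float
    kidney_center_z: float
    kidney_length: float
    neck_bottom_z: float
    is_pediatric: bool = False
    voxel_spacing: tuple[float, float, float] = (2.5, 2.5, 5.0)  # mm
    seed: int = 0
    noise_hu: float = 0.0

    def __post_init__(self) -> None:
        if not (100.0 <= self.height <= 200.0):
            raise ValueError(f"height {self.height} cm outside supported range 100-200 cm")
        for name in ("shoulder_width", "umbilicus_separation", "leg_width",
                     "lung_length", "kidney_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.leg_width > 35.0:
            raise ValueError(
                f"leg_width {self.leg_width} cm exceeds the 35 cm AP/PA eligibility limit"
            )
        if self.lung_bottom_z <= self.kidney_top_z:
            raise ValueError(
                "lung_center_z/kidney_center_z invalid: lungs must be strictly "
                "superior to kidneys"
            )
        if self.neck_bottom_z <= self.lung_center_z:
            raise ValueError("neck_bottom_z must be superior to lung_center_z")
        if self.neck_bottom_z >= self.head_top_z:
            raise ValueError("neck_bottom_z must be inferior to the top of the head")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive")

    # --- derived landmarks (cm, pelvis-mark frame) -------------------------
    @property
    def head_top_z(self) -> float:
        return (1.0 - PELVIS_FRACTION) * self.height

    @property
    def feet_bottom_z(self) -> float:
        return -PELVIS_FRACTION * self.height

    @property
    def legs_top_z(self) -> float:
        return self.feet_bottom_z + 0.48 * self.height

    @property
    def lung_bottom_z(self) -> float:
        return self.lung_center_z - self.lung_length / 2.0

    @property
    def kidney_top_z(self) -> float:
        return self.kidney_center_z + self.kidney_length / 2.0

    @property
    def lung_kidney_gap_cm(self) -> float:
        return self.lung_bottom_z - self.kidney_top_z

    # --- factories ---------------------------------------------------------
    @classmethod
    def default_adult(cls, height: float = 180.0, seed: int = 0, **overrides) -> "PhantomSpec":
        """Adult proportions scaled from height (anthropometric defaults)."""
        h = height
        head_top = (1.0 - PELVIS_FRACTION) * h
        base = dict(
            height=h,
            shoulder_width=0.25 * h,
            umbilicus_separation=float(np.clip(0.12 * h, 14.3, 33.0)),
            leg_width=min(0.10 * h, 35.0),
            lung_center_z=0.205 * h,
            lung_length=0.12 * h,
            kidney_center_z=0.075 * h,
            kidney_length=0.06 * h,
            neck_bottom_z=head_top - min(24.0, 0.16 * h),
            is_pediatric=False,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def default_pediatric(cls, height: float = 140.0, seed: int = 0, **overrides) -> "PhantomSpec":
        over = dict(is_pediatric=True)
        over.update(overrides)
        return cls.default_adult(height, seed=seed, **over)


def _ellipsoid(X, Y, Z, cx, cy, cz, ax, ay, az):
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, StructureSet]:
    """Rasterize a phantom CT and its structure set.

    Deterministic for a fixed spec (including seed).  The body z extent
    equals ``spec.height`` to within one voxel.
    """
    sp = spec.voxel_spacing
    head_half_x = 75.0  # mm, cranium lateral semi-axis
    head_half_y = 95.0
    half_x = max(_cm(spec.shoulder_width) / 2.0, head_half_x) + 20.0
    half_y = max(_cm(spec.umbilicus_separation) / 2.0, head_half_y) + 30.0
    z_lo = _cm(spec.feet_bottom_z) - 30.0
    z_hi = _cm(spec.head_top_z) + 30.0
    grid = Grid.covering((-half_x, -half_y, z_lo), (half_x, half_y, z_hi), sp)

    X = grid.axis_coords(0)[:, None, None]
    Y = grid.axis_coords(1)[None, :, None]
    Z = grid.axis_coords(2)[None, None, :]

    feet = _cm(spec.feet_bottom_z)
    legs_top = _cm(spec.legs_top_z)
    neck_bottom = _cm(spec.neck_bottom_z)
    head_top = _cm(spec.head_top_z)

    # trunk: elliptic cylinder
    a_tr = _cm(spec.shoulder_width) / 2.0
    b_tr = _cm(spec.umbilicus_separation) / 2.0
    trunk = ((X / a_tr) ** 2 + (Y / b_tr) ** 2 <= 1.0) & (Z >= legs_top) & (Z < neck_bottom)

    # legs: two overlapping cylinders (adducted legs touch at the midline,
    # so the isocenter line runs through tissue, not air)
    r_leg = _cm(spec.leg_width) / 3.6
    legs = np.zeros(grid.shape, dtype=bool)
    for cx in (-0.8 * r_leg, 0.8 * r_leg):
        legs |= (((X - cx) / r_leg) ** 2 + (Y / r_leg) ** 2 <= 1.0) & (Z >= feet) & (Z < legs_top)

    # head: neck cylinder + cranial ellipsoid ending exactly at head_top
    head_len = head_top - neck_bottom
    neck = (
        (X**2 + Y**2 <= 55.0**2)
        & (Z >= neck_bottom)
        & (Z < neck_bottom + 0.40 * head_len)
    )
    cranium = _ellipsoid(
        X, Y, Z,
        0.0, 0.0, neck_bottom + 0.55 * head_len,
        min(head_half_x, a_tr), min(head_half_y, max(b_tr, 80.0)), 0.45 * head_len,
    )
    body = trunk | legs | neck | cranium

    # lungs: paired ellipsoids in the chest
    s = _cm(spec.shoulder_width)
    u = _cm(spec.umbilicus_separation)
    lungs = np.zeros(grid.shape, dtype=bool)
    for cx in (-0.2 * s, 0.2 * s):
        lungs |= _ellipsoid(
            X, Y, Z,
            cx, 0.0, _cm(spec.lung_center_z),
            s / 8.0, u / 3.0, _cm(spec.lung_length) / 2.0,
        )
    lungs &= body

    kidneys = np.zeros(grid.shape, dtype=bool)
    for cx in (-0.12 * s, 0.12 * s):
        kidneys |= _ellipsoid(
            X, Y, Z,
            cx, -0.15 * u, _cm(spec.kidney_center_z),
            s / 10.0, u / 6.0, _cm(spec.kidney_length) / 2.0,
        )
    kidneys &= body

    hu = np.full(grid.shape, AIR_HU, dtype=np.float32)
    hu[body] = BODY_HU
    hu[lungs] = LUNG_HU

    # pelvis fiducial markers (the marked reference point plus two offset
    # marks): without them the smooth trunk would leave the two-scan
    # registration unidentifiable along z, unlike a real bony pelvis
    for mx, my, mz in ((0.0, 0.0, 0.0), (50.0, -30.0, 35.0), (-50.0, 30.0, -35.0)):
        marker = ((X - mx) ** 2 + (Y - my) ** 2 + (Z - mz) ** 2) <= 8.0**2
        hu[marker & body] = 800.0
    if spec.noise_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_hu, grid.shape).astype(np.float32)

    volume = ImageVolume(grid, hu, "HFS")
    structures = StructureSet(
        grid,
        {"body": body, "lungs": lungs, "kidneys": kidneys},
        {
            "head_top": head_top,
            "neck_bottom": neck_bottom,
            "legs_top": legs_top,
            "feet_bottom": feet,
        },
    )
    structures.validate()
    return volume, structures


def split_scans(
    whole: ImageVolume,
    structures: StructureSet,
    overlap_cm: float = 10.0,
    applied_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[ImageVolume, ImageVolume, tuple[float, float, float]]:
    """Cut the whole-body volume into a head-first and a feet-first scan.

    The SHF scan covers from above the head to ``overlap/2`` below the
    pelvis mark; the SFF scan covers from below the feet to ``overlap/2``
    above the mark and is resampled with a known rigid ``applied_offset``
    (mm, patient axes) emulating the setup change between acquisitions.
    Returns ``(shf, sff, truth)`` where ``truth`` echoes the offset that a
    registration must recover.  The SFF scan is stored feet-first (z and x
    voxel order flipped relative to patient coordinates).
    """
    offset = np.asarray(applied_offset, dtype=float)
    if np.any(np.abs(offset) > 20.0):
        raise ValueError("applied_offset must be at most 20 mm per axis")
    half = _cm(overlap_cm) / 2.0
    legs_top = structures.landmarks.get("legs_top")
    lo_ext, hi_ext = whole.grid.extent
    if half <= 0 or -half < lo_ext[2] or half > hi_ext[2]:
        raise ValueError("overlap region is empty or outside the scanned volume")
    if legs_top is not None and -half < legs_top - 250.0:
        raise ValueError("overlap region extends below the pelvis")

    shf = whole.crop_z(-half, hi_ext[2])

    sff_patient = whole.crop_z(lo_ext[2], half)
    if np.any(np.abs(offset) > 0):
        # scan records content displaced by +offset: S(p) = W(p - offset)
        g = sff_patient.grid
        xs = g.axis_coords(0) - offset[0]
        ys = g.axis_coords(1) - offset[1]
        zs = g.axis_coords(2) - offset[2]
        pts = np.stack(
            [c.ravel() for c in np.meshgrid(xs, ys, zs, indexing="ij")], axis=1
        )
        vals = whole.sample(pts).reshape(g.shape).astype(np.float32)
        sff_patient = ImageVolume(g, vals, "HFS")
    sff = sff_patient.to_ffs()
    return shf, sff, tuple(float(v) for v in offset)
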