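"""Beam geometry and a transparent primary-beam dose engine.

The engine is deliberately simple so that every junction property is
analytically checkable: dose at a voxel inside a segment aperture is

    MU * 0.01 Gy/MU * weight * (SAD / d_src)^2 * A(WED) * T_block

where ``d_src`` is the distance from the source along the beam axis,
``WED`` the water-equivalent depth (parallel-ray line integral of relative
density along the beam direction), ``A`` a linear build-up to ``dmax``
followed by exponential attenuation, and ``T_block`` the transmission of
any shielding block whose beam's-eye-view shadow covers the voxel.  Voxels
outside every aperture receive exactly zero (no penumbra model).

Beam coordinates: with collimator 0 and gantry 0 (source anterior), the
aperture x axis is the patient longitudinal axis would-be after a 90-degree
collimator twist; concretely the beam's-eye-view basis is

    d  = (-sin g, -cos g, 0)                     beam direction
    u0 = (cos g, -sin g, 0),  v0 = (0, 0, 1)
    u  =  cos c * u0 + sin c * v0
    v  = -sin c * u0 + cos c * v0

so with the collimator at 90 degrees (the standard setting here) the
aperture x interval selects patient-z and the y interval the lateral axis,
for every gantry angle.  Apertures are rectangles at the isocenter plane
in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .segmentation import SegmentationParams, SubTarget
from .volumes import DoseGrid, Grid, ImageVolume

__all__ = [
    "PhysicsConstants",
    "BeamSegment",
    "Block",
    "Beam",
    "DVHMetrics",
    "beam_basis",
    "compute_beam_dose",
    "make_feathered_appa",
    "make_step_wedge",
    "optimize_segment_weights",
    "vmat_surrogate_dose",
    "compute_dvh",
    "lung_dose_rate",
    "density_from_hu",
    "default_dose_grid",
]

DOSE_PER_MU_GY = 0.01  # calibration: 1 MU -> 1 cGy at dmax, SAD, open field


@dataclass(frozen=True)
class PhysicsConstants:
    """Engineering defaults for the primary-beam model (per-energy keys MV)."""

    mu_eff_per_cm: dict = field(default_factory=lambda: {6: 0.049, 10: 0.044})
    dmax_cm: dict = field(default_factory=lambda: {6: 1.5, 10: 2.5})
    lung_density: float = 0.3
    cerrobend_density: float = 9.4  # g/cm3
    cerrobend_mu_per_cm: dict = field(default_factory=lambda: {6: 0.49, 10: 0.43})
    lucite_density: float = 1.18  # g/cm3
    ray_step_mm: float = 2.5

    def __post_init__(self) -> None:
        for d in (self.mu_eff_per_cm, self.dmax_cm, self.cerrobend_mu_per_cm):
            if any(v <= 0 for v in d.values()):
                raise ValueError("physics constants must be positive")
        if self.lung_density <= 0 or self.ray_step_mm <= 0:
            raise ValueError("physics constants must be positive")


@dataclass(frozen=True)
class BeamSegment:
    """Rectangular aperture (cm, isocenter plane, beam coords) + weight."""

    aperture: tuple[float, float, float, float]  # x1, x2, y1, y2
    relative_weight: float = 1.0

    def __post_init__(self) -> None:
        x1, x2, y1, y2 = self.aperture
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"degenerate aperture {self.aperture}")
        if self.relative_weight < 0:
            raise ValueError("segment weight must be non-negative")


@dataclass(frozen=True)
class Block:
    """Shielding block: a beam's-eye-view shadow mask with a thickness."""

    u_coords: np.ndarray  # mm, isocenter plane
    v_coords: np.ndarray
    mask: np.ndarray  # (len(u), len(v)) bool
    thickness_cm: float
    mu_per_cm: float

    def transmission(self, up: np.ndarray, vp: np.ndarray) -> np.ndarray:
        """Attenuation factor for rays whose BEV coordinates are (up, vp) mm."""
        if self.mask.size == 0 or not self.mask.any():
            return np.ones_like(up)
        du = self.u_coords[1] - self.u_coords[0] if len(self.u_coords) > 1 else 1.0
        dv = self.v_coords[1] - self.v_coords[0] if len(self.v_coords) > 1 else 1.0
        iu = np.rint((up - self.u_coords[0]) / du).astype(int)
        iv = np.rint((vp - self.v_coords[0]) / dv).astype(int)
        inside = (
            (iu >= 0) & (iu < len(self.u_coords)) & (iv >= 0) & (iv < len(self.v_coords))
        )
        hit = np.zeros(up.shape, dtype=bool)
        hit[inside] = self.mask[iu[inside], iv[inside]]
        t = np.ones_like(up)
        t[hit] = math.exp(-self.mu_per_cm * self.thickness_cm)
        return t


@dataclass
class Beam:
    """A deliverable beam: geometry, energy, monitor units, segments."""

    isocenter: tuple[float, float, float]  # mm
    gantry: float  # deg, [0, 360)
    collimator: float  # deg
    couch: float = 0.0
    energy: int = 6  # MV
    sad_cm: float = 100.0
    mu: float = 100.0
    mu_rate: float = 600.0  # MU/min
    segments: list[BeamSegment] = field(default_factory=list)
    technique: str = "feathered_appa"
    blocks: list[Block] = field(default_factory=list)
    spoiler_wed_mm: float = 0.0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gantry = self.gantry % 360.0
        self.collimator = self.collimator % 360.0
        if self.energy not in (6, 10):
            raise ValueError("energy must be 6 or 10 MV")
        if self.mu < 0 or self.mu_rate <= 0:
            raise ValueError("mu must be >= 0 and mu_rate positive")

    def normalized_segments(self) -> list[BeamSegment]:
        total = sum(s.relative_weight for s in self.segments)
        if total <= 0:
            raise ValueError("beam has no positive segment weight")
        return [replace(s, relative_weight=s.relative_weight / total) for s in self.segments]


@dataclass(frozen=True)
class DVHMetrics:
    """Vx (% of volume at >= x% of prescription) and mean dose per structure."""

    vx: dict  # {100: %, 95: %, 90: %, 110: %}
    dmean_gy: float


def beam_basis(gantry: float, collimator: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = math.radians(gantry)
    c = math.radians(collimator)
    d = np.array([-math.sin(g), -math.cos(g), 0.0])
    u0 = np.array([math.cos(g), -math.sin(g), 0.0])
    v0 = np.array([0.0, 0.0, 1.0])
    u = math.cos(c) * u0 + math.sin(c) * v0
    v = -math.sin(c) * u0 + math.cos(c) * v0
    return d, u, v


def density_from_hu(hu: np.ndarray, constants: PhysicsConstants) -> np.ndarray:
    """Piecewise relative density: air 0, lung override, soft tissue 1."""
    rho = np.ones(hu.shape, dtype=np.float64)
    rho[hu < -350.0] = constants.lung_density
    rho[hu < -950.0] = 0.0
    return rho


def default_dose_grid(ct: ImageVolume, spacing_mm: float = 5.0) -> Grid:
    """Isotropic dose grid whose voxel centres lie on the CT centre lattice
    (keeps nearest-neighbour resampling stable under exact frame flips)."""
    origin, shape = [], []
    for ax in range(3):
        o = ct.grid.origin[ax]
        last = o + (ct.grid.shape[ax] - 1) * ct.grid.spacing[ax]
        n = int(np.floor((last - o) / spacing_mm)) + 1
        origin.append(o)
        shape.append(max(1, n))
    return Grid(tuple(origin), (spacing_mm,) * 3, tuple(shape))


def _ray_exit_lengths(P: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Distance from each point backwards along -d to the bounding box edge."""
    L = np.full(P.shape[0], np.inf)
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            continue
        # travelling along -d: parameter t >= 0 at q = P - t*d
        t1 = (P[:, ax] - lo[ax]) / d[ax]
        t2 = (P[:, ax] - hi[ax]) / d[ax]
        L = np.minimum(L, np.maximum(t1, t2))
    return np.maximum(L, 0.0)


def _water_equivalent_depth(
    P: np.ndarray,
    d: np.ndarray,
    density: np.ndarray,
    ct_grid: Grid,
    step_mm: float,
) -> np.ndarray:
    """Parallel-ray WED (mm of water) from the surface to each point."""
    lo, hi = ct_grid.extent
    exit_len = _ray_exit_lengths(P, d, lo, hi)
    n_steps = int(np.ceil(exit_len.max() / step_mm)) if P.shape[0] else 0
    wed = np.zeros(P.shape[0], dtype=np.float64)
    origin = np.asarray(ct_grid.origin)
    spacing = np.asarray(ct_grid.spacing)
    for k in range(n_steps):
        t = (k + 0.5) * step_mm
        active = exit_len > t - step_mm  # sample up to (and including) the exit step
        if not active.any():
            break
        q = P[active] - d * t
        idx = ((q - origin) / spacing).T
        rho = ndimage.map_coordinates(
            density, idx, order=1, mode="constant", cval=0.0, prefilter=False
        )
        wed[active] += rho * step_mm
    return wed


def _attenuation(wed_mm: np.ndarray, energy: int, constants: PhysicsConstants) -> np.ndarray:
    dmax = constants.dmax_cm[energy] * 10.0
    mu = constants.mu_eff_per_cm[energy] / 10.0
    a = np.empty(wed_mm.shape, dtype=np.float64)
    build = wed_mm < dmax
    a[build] = wed_mm[build] / dmax
    a[~build] = np.exp(-mu * (wed_mm[~build] - dmax))
    return a


class BeamKernel:
    """Cached per-beam geometry for repeated dose evaluation.

    The beam's-eye-view projection, inverse-square factor, water-equivalent
    depth, and block transmission of a beam do not depend on its segment
    apertures or weights, so they are computed once over the candidate
    voxels (the aperture union) and reused when segment weights change
    during optimization.
    """

    def __init__(
        self,
        beam: Beam,
        ct: ImageVolume,
        constants: PhysicsConstants | None = None,
        grid: Grid | None = None,
        density: np.ndarray | None = None,
        body_only: bool = True,
    ) -> None:
        constants = constants or PhysicsConstants()
        grid = grid or default_dose_grid(ct)
        if density is None:
            density = density_from_hu(ct.values, constants)
        self.beam = beam
        self.grid = grid
        self.constants = constants

        if body_only:
            from .volumes import resample_to_grid

            rho_d = resample_to_grid(
                ImageVolume(ct.grid, density), grid, order=0, cval=0.0
            ).values
            cand = np.nonzero(rho_d > 0.05)
        else:
            cand = np.nonzero(np.ones(grid.shape, dtype=bool))
        self.cand = cand
        xs, ys, zs = (grid.axis_coords(i) for i in range(3))
        P = np.stack([xs[cand[0]], ys[cand[1]], zs[cand[2]]], axis=1)

        d, u, v = beam_basis(beam.gantry, beam.collimator)
        iso = np.asarray(beam.isocenter, dtype=float)
        sad = beam.sad_cm * 10.0
        source = iso - sad * d
        w = P - source
        t_axis = w @ d
        self.valid = t_axis > 1.0
        scale = np.where(self.valid, sad / np.where(self.valid, t_axis, 1.0), 0.0)
        self.up = (w @ u) * scale
        self.vp = (w @ v) * scale

        hit = np.zeros(P.shape[0], dtype=bool)
        for seg in beam.segments:
            hit |= self._inside(seg)
        core = np.zeros(P.shape[0], dtype=np.float64)
        if hit.any():
            wed = _water_equivalent_depth(
                P[hit], d, density, ct.grid, constants.ray_step_mm
            )
            wed = wed + beam.spoiler_wed_mm
            att = _attenuation(wed, beam.energy, constants)
            core_hit = DOSE_PER_MU_GY * (scale[hit] ** 2) * att
            for blk in beam.blocks:
                core_hit *= blk.transmission(self.up[hit], self.vp[hit])
            core[hit] = core_hit
        self.core = core  # Gy per MU per unit segment weight, pre-fluence

    def _inside(self, seg: BeamSegment) -> np.ndarray:
        x1, x2, y1, y2 = (a * 10.0 for a in seg.aperture)
        return (
            (self.up >= x1) & (self.up <= x2)
            & (self.vp >= y1) & (self.vp <= y2)
            & self.valid
        )

    def segment_unit_values(self, seg: BeamSegment) -> np.ndarray:
        """Dose per MU at the candidate voxels for one unit-weight segment."""
        out = np.zeros(self.core.shape, dtype=np.float64)
        inside = self._inside(seg)
        out[inside] = self.core[inside]
        return out

    def dose(self, beam: Beam | None = None) -> DoseGrid:
        """Full dose grid for the (possibly re-weighted) beam."""
        beam = beam or self.beam
        fluence = np.zeros(self.core.shape, dtype=np.float64)
        for seg in beam.normalized_segments():
            fluence[self._inside(seg)] += seg.relative_weight
        vals = np.zeros(self.grid.shape, dtype=np.float64)
        vals[self.cand] = beam.mu * fluence * self.core
        return DoseGrid(self.grid, vals)


def dose_at_points(
    beam: Beam,
    points: np.ndarray,
    ct: ImageVolume,
    constants: PhysicsConstants | None = None,
    density: np.ndarray | None = None,
) -> np.ndarray:
    """Primary dose (Gy) of one physical beam at arbitrary world points."""
    constants = constants or PhysicsConstants()
    if density is None:
        density = density_from_hu(ct.values, constants)
    P = np.atleast_2d(np.asarray(points, dtype=float))
    d, u, v = beam_basis(beam.gantry, beam.collimator)
    iso = np.asarray(beam.isocenter, dtype=float)
    sad = beam.sad_cm * 10.0
    source = iso - sad * d
    w = P - source
    t_axis = w @ d
    valid = t_axis > 1.0
    out = np.zeros(P.shape[0], dtype=np.float64)
    if not valid.any():
        return out
    scale = np.where(valid, sad / np.where(valid, t_axis, 1.0), 0.0)
    up = (w @ u) * scale  # mm at the isocenter plane
    vp = (w @ v) * scale

    fluence = np.zeros(P.shape[0], dtype=np.float64)
    for seg in beam.normalized_segments():
        x1, x2, y1, y2 = (a * 10.0 for a in seg.aperture)
        inside = (up >= x1) & (up <= x2) & (vp >= y1) & (vp <= y2) & valid
        fluence[inside] += seg.relative_weight
    hit = fluence > 0
    if not hit.any():
        return out

    wed = _water_equivalent_depth(P[hit], d, density, ct.grid, constants.ray_step_mm)
    wed = wed + beam.spoiler_wed_mm
    att = _attenuation(wed, beam.energy, constants)
    result = (
        DOSE_PER_MU_GY
        * beam.mu
        * fluence[hit]
        * (scale[hit] ** 2)
        * att
    )
    for blk in beam.blocks:
        result *= blk.transmission(up[hit], vp[hit])
    out[hit] = result
    return out


def compute_beam_dose(
    beam: Beam,
    ct: ImageVolume,
    constants: PhysicsConstants | None = None,
    grid: Grid | None = None,
    body_only: bool = True,
    density: np.ndarray | None = None,
) -> DoseGrid:
    """Primary-only dose of one beam on a (default 5 mm) dose grid.

    ``body_only`` restricts evaluation to voxels with non-zero density
    (dose to air is irrelevant for every downstream metric).  Doubling the
    MU doubles the dose exactly; segment weights are normalized to 1.
    """
    constants = constants or PhysicsConstants()
    if beam.technique == "vmat_arc_surrogate":
        from . import planning

        return planning.surrogate_beam_dose(beam, ct, grid=grid, constants=constants)
    grid = grid or default_dose_grid(ct)
    if density is None:
        density = density_from_hu(ct.values, constants)
    dose = np.zeros(grid.shape, dtype=np.float64)

    if body_only:
        from .volumes import resample_to_grid

        rho_d = resample_to_grid(
            ImageVolume(ct.grid, density), grid, order=0, cval=0.0
        ).values
        cand = np.nonzero(rho_d > 0.05)
    else:
        cand = np.nonzero(np.ones(grid.shape, dtype=bool))
    if cand[0].size == 0:
        import warnings

        warnings.warn("beam misses the volume; returning zero dose", stacklevel=2)
        return DoseGrid(grid, dose)
    xs, ys, zs = (grid.axis_coords(i) for i in range(3))
    P = np.stack([xs[cand[0]], ys[cand[1]], zs[cand[2]]], axis=1)
    vals = dose_at_points(beam, P, ct, constants, density=density)
    if not np.any(vals):
        import warnings

        warnings.warn("beam misses the volume; returning zero dose", stacklevel=2)
    dose[cand] = vals
    return DoseGrid(grid, dose)


# --------------------------------------------------------------------------
# Beam constructors
# --------------------------------------------------------------------------

APPA_MAX_HALF_FIELD_CM = 20.0  # maximum jaw opening from the isocenter


def make_feathered_appa(
    subtarget: SubTarget,
    params: SegmentationParams | None = None,
    energy: int = 6,
    lateral_half_cm: float = 20.0,
    is_last: bool = False,
    feather_superior: bool = True,
    feather_inferior: bool = True,
) -> tuple[Beam, Beam]:
    """AP/PA beam pair for a leg/feet sub-target: collimator 90, three
    nested rectangular segments stepping the longitudinal edges across the
    feathering zones.  For the most inferior sub-target the inferior edge
    is fixed at the maximum opening to cover past the feet."""
    params = params or SegmentationParams()
    if subtarget.kind != "APPA":
        raise ValueError(f"sub-target {subtarget.index} is not an AP/PA sub-target")
    h = params.ofz_halfwidth  # cm
    iso_z = subtarget.isocenter[2]
    lo = (subtarget.z_interval[0] - iso_z) / 10.0  # cm relative to isocenter
    hi = (subtarget.z_interval[1] - iso_z) / 10.0
    segments = []
    for j in range(3):
        sup = hi + h - j * h if feather_superior else hi + h
        if is_last or not feather_inferior:
            inf = -APPA_MAX_HALF_FIELD_CM if is_last else lo - h
        else:
            inf = lo - h + j * h
        segments.append(BeamSegment((inf, sup, -lateral_half_cm, lateral_half_cm), 1.0))
    beams = []
    for gantry in (0.0, 180.0):
        beams.append(
            Beam(
                isocenter=subtarget.isocenter,
                gantry=gantry,
                collimator=90.0,
                energy=energy,
                mu=100.0,
                mu_rate=600.0,
                segments=[replace(s) for s in segments],
                technique="feathered_appa",
                label=f"APPA{subtarget.index}_{'AP' if gantry == 0 else 'PA'}",
                meta={"subtarget_index": subtarget.index},
            )
        )
    return beams[0], beams[1]


def make_step_wedge(
    junction_point: tuple[float, float, float],
    params: SegmentationParams | None = None,
    ascending: str = "inferior",
    lateral_half_cm: float = 17.5,
    energy: int = 6,
    mu: float = 100.0,
) -> list[Beam]:
    """Nine equally weighted step-and-shoot beams, gantry angles 40 degrees
    apart, each with 5 equal-weight nested segments whose longitudinal
    edges advance in 1 cm steps across the junction, producing a staircase
    fluence that ramps monotonically (ascending toward ``ascending``)."""
    params = params or SegmentationParams()
    if ascending not in ("inferior", "superior"):
        raise ValueError("ascending must be 'inferior' or 'superior'")
    h = params.ofz_halfwidth  # 2.5 cm
    width = 2.0 * h  # 5 cm junction
    step = width / 5.0  # 1 cm
    plateau = h  # full-intensity margin beyond the junction
    segments = []
    for k in range(5):
        if ascending == "inferior":
            sup = h - k * step  # edges advance down in 1 cm steps
            inf = -h - plateau
        else:
            inf = -h + k * step
            sup = h + plateau
        segments.append(BeamSegment((inf, sup, -lateral_half_cm, lateral_half_cm), 1.0))
    beams = []
    for i in range(9):
        beams.append(
            Beam(
                isocenter=tuple(junction_point),
                gantry=i * 40.0,
                collimator=90.0,
                energy=energy,
                mu=mu / 9.0,
                mu_rate=600.0,
                segments=[replace(s) for s in segments],
                technique="step_wedge",
                label=f"wedge_g{i * 40}",
            )
        )
    return beams


# --------------------------------------------------------------------------
# Segment weight optimization
# --------------------------------------------------------------------------


def optimize_segment_weights(
    beams: list[Beam],
    target: np.ndarray,
    ct: ImageVolume,
    constants: PhysicsConstants | None = None,
    rx: float = 1.0,
    grid: Grid | None = None,
    ramp_target: tuple[np.ndarray, np.ndarray] | None = None,
    max_points: int = 4000,
    kernels: list["BeamKernel"] | None = None,
    smoothness: float = 1e-3,
) -> tuple[list[Beam], np.ndarray]:
    """Non-negative least-squares segment weights for a uniform target dose.

    ``target`` is a boolean mask on ``grid`` receiving ``rx``;
    ``ramp_target`` optionally adds (mask, desired_gy) voxels, used for the
    complementary ramp across a junction.  Returns re-weighted copies of
    the beams (weights normalized per beam, MU absorbing the scale) and the
    raw per-segment scales.  The achieved objective never exceeds the
    best-scaled equal-weights objective.
    """
    from scipy.optimize import nnls

    constants = constants or PhysicsConstants()
    grid = grid or default_dose_grid(ct)
    if not any(b.segments for b in beams):
        raise ValueError("no segments to optimize")
    if kernels is None:
        density = density_from_hu(ct.values, constants)
        kernels = [
            BeamKernel(b, ct, constants, grid=grid, density=density) for b in beams
        ]

    # map sample voxels (flat grid indices) into each kernel's candidate list
    flat_cand = np.ravel_multi_index(kernels[0].cand, grid.shape)
    pos_of_flat = -np.ones(int(np.prod(grid.shape)), dtype=np.int64)
    pos_of_flat[flat_cand] = np.arange(flat_cand.size)

    idx = np.nonzero(target.ravel())[0]
    stride = max(1, idx.size // max_points)
    idx = idx[::stride]
    b_vec = np.full(idx.size, rx, dtype=float)
    if ramp_target is not None:
        rmask, rvals = ramp_target
        ridx = np.nonzero(rmask.ravel())[0]
        rstride = max(1, ridx.size // max_points)
        ridx = ridx[::rstride]
        idx = np.concatenate([idx, ridx])
        b_vec = np.concatenate([b_vec, np.asarray(rvals).ravel()[ridx]])
    sample_pos = pos_of_flat[idx]
    known = sample_pos >= 0

    rows = []
    owners = []
    for bi, (b, k) in enumerate(zip(beams, kernels)):
        for si, seg in enumerate(b.segments):
            vals = k.segment_unit_values(seg)
            col = np.zeros(idx.size, dtype=float)
            col[known] = vals[sample_pos[known]]
            rows.append(col)
            owners.append((bi, si))
    A = np.stack(rows, axis=1).astype(float)
    # weak intra-beam smoothness rows break active-set ties between
    # segments whose uniform-region doses are indistinguishable; without
    # them the solver returns sparse weights that collapse the feathering
    # staircase to fewer steps
    if smoothness > 0:
        extra = []
        for bi in {o[0] for o in owners}:
            cols = [k for k, (obi, _) in enumerate(owners) if obi == bi]
            for i, j in zip(cols, cols[1:]):
                row = np.zeros(A.shape[1])
                row[i], row[j] = smoothness, -smoothness
                extra.append(row)
        if extra:
            A = np.vstack([A, np.asarray(extra)])
            b_vec = np.concatenate([b_vec, np.zeros(len(extra))])
    w, _ = nnls(A, b_vec)
    if not np.any(w > 0):
        raise ValueError("segment weight optimization returned the all-zero solution")

    # contract check against best-scaled equal weights
    e = np.ones_like(w)
    Ae = A @ e
    scale = float(Ae @ b_vec / (Ae @ Ae)) if Ae.any() else 0.0
    obj = float(np.sum((A @ w - b_vec) ** 2))
    obj_eq = float(np.sum((Ae * scale - b_vec) ** 2))
    if obj > obj_eq + 1e-6 * max(obj_eq, 1.0):
        w = e * scale  # defensive; NNLS should always be at least as good

    out_beams = []
    for bi, b in enumerate(beams):
        ws = [w[k] for k, (obi, _) in enumerate(owners) if obi == bi]
        total = sum(ws)
        if total <= 0:
            segs = [replace(s, relative_weight=0.0) for s in b.segments]
            out_beams.append(replace(b, mu=0.0, segments=segs))
            continue
        segs = [
            replace(s, relative_weight=wk / total) for s, wk in zip(b.segments, ws)
        ]
        # unit-MU segment doses were used, so the summed scale is the beam MU
        out_beams.append(replace(b, mu=float(total), segments=segs))
    return out_beams, w


# --------------------------------------------------------------------------
# VMAT surrogate and metrics
# --------------------------------------------------------------------------


def vmat_surrogate_dose(
    subtarget: SubTarget,
    base_dose: DoseGrid | None,
    rx: float,
    ct: ImageVolume,
    grid: Grid | None = None,
    constants: PhysicsConstants | None = None,
    lung_mask: np.ndarray | None = None,
    lung_scale: float | None = None,
) -> DoseGrid:
    """Idealized achieved dose of an optimized VMAT sub-target.

    Inside the optimization interval (body voxels only) the dose is the
    prescription minus the base dose — the distribution the junction base
    dose forces the optimizer toward — clipped at zero, with a half-voxel
    linear rolloff at non-junction interval edges.  Zero outside.
    """
    if subtarget.kind != "VMAT":
        raise ValueError("surrogate dose applies to VMAT sub-targets only")
    constants = constants or PhysicsConstants()
    grid = grid or default_dose_grid(ct)
    from .volumes import resample_to_grid

    density = density_from_hu(ct.values, constants)
    rho = resample_to_grid(ImageVolume(ct.grid, density), grid, order=0, cval=0.0).values
    body = rho > 0.05

    zc = grid.axis_coords(2)
    hz = grid.spacing[2] / 2.0
    lo, hi = subtarget.opt_interval
    cover = np.clip((np.minimum(zc + hz, hi) - np.maximum(zc - hz, lo)) / (2 * hz), 0.0, 1.0)
    mask3 = body & (cover[None, None, :] > 0)

    if base_dose is not None:
        if not base_dose.grid.same_geometry(grid):
            raise ValueError("base dose grid does not match the dose grid")
        base = base_dose.values
        if np.any(base[mask3] > rx * (1.0 + 1e-6)):
            raise ValueError("base dose exceeds the prescription inside the optimization interval")
    else:
        base = 0.0

    vals = np.zeros(grid.shape, dtype=np.float64)
    full = np.clip(rx - base, 0.0, None)
    if np.isscalar(full):
        full = np.full(grid.shape, full, dtype=np.float64)
    vals[mask3] = (full * cover[None, None, :])[mask3]
    if lung_mask is not None and lung_scale is not None:
        vals[lung_mask & mask3] *= float(lung_scale)
    return DoseGrid(grid, vals)


def compute_dvh(
    dose: DoseGrid,
    mask: np.ndarray,
    rx: float,
    levels: tuple[int, ...] = (100, 95, 90, 110),
) -> DVHMetrics:
    """Vx = % of mask voxels with dose >= x% of rx; Dmean in Gy."""
    if mask.shape != tuple(dose.grid.shape):
        raise ValueError("mask grid does not match the dose grid")
    if not mask.any():
        raise ValueError("empty structure mask")
    d = dose.values[mask]
    vx = {
        x: float(100.0 * np.count_nonzero(d >= (x / 100.0) * rx) / d.size)
        for x in levels
    }
    return DVHMetrics(vx=vx, dmean_gy=float(d.mean()))


def lung_dose_rate(
    lung_iso_beams: list[Beam],
    lung_dose_per_fraction_gy: float,
) -> float:
    """Mean lung dose rate in cGy/min: lung dose per fraction from the
    lung-isocenter beams divided by their beam-on time.  Scales inversely
    with the MU rate."""
    if not lung_iso_beams:
        raise ValueError("no lung-isocenter beams identified")
    beam_on_min = sum(b.mu / b.mu_rate for b in lung_iso_beams)
    if beam_on_min <= 0:
        raise ValueError("zero beam-on time (beams have no MU)")
    return 100.0 * lung_dose_per_fraction_gy / beam_on_min
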