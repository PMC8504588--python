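"""PTV construction and rule-based division into sub-targets.

The planning target volume (PTV) is the body contracted in from the skin,
excluding lungs and kidneys.  It is divided longitudinally into VMAT
sub-targets (head first, then fixed-length blocks down to the legs) and
equal-length AP/PA sub-targets covering legs and feet, each extended by an
optimization feathering zone (OFZ) so that adjacent optimization volumes
overlap by a fixed junction width.  Isocenters sit at sub-target centres,
junction points at junction-region centres, and all points share the same
lateral/vertical coordinates.

Lengths are handled in cm at the interface (matching clinical usage) and
mm internally; intervals are half-open, superior-exclusive: [inferior,
superior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .volumes import Grid, StructureSet

__all__ = [
    "SegmentationParams",
    "SubTarget",
    "SubTargetSet",
    "VmatLimits",
    "build_ptv",
    "compute_vmat_limit",
    "appa_length_lookup",
    "divide_ptv",
    "pediatric_adjust",
    "large_patient_adjust",
]


class VmatLimits(NamedTuple):
    field_length: float  # cm, split-arc field span
    opt_limit: float  # cm, optimization sub-target (sub-target + OFZ) limit
    subtarget_limit: float  # cm, VMAT sub-target limit


def compute_vmat_limit(
    mlc_travel_limit: float, field_margin_per_side: float, ofz_width: float
) -> VmatLimits:
    """Derive VMAT length limits from machine constraints (all cm).

    Split arcs double the usable MLC travel to the field length; the
    optimization-target limit subtracts a field margin on each side; the
    sub-target limit additionally subtracts the feathering-zone width.
    """
    if mlc_travel_limit <= 0 or field_margin_per_side < 0 or ofz_width < 0:
        raise ValueError("machine constraint inputs must be positive")
    field_length = 2.0 * mlc_travel_limit
    opt_limit = field_length - 2.0 * field_margin_per_side
    subtarget_limit = opt_limit - ofz_width
    if subtarget_limit <= 0:
        raise ValueError(
            f"derived sub-target limit {subtarget_limit} cm is not positive; "
            "check margins and feathering width"
        )
    return VmatLimits(field_length, opt_limit, subtarget_limit)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the sub-target division rules.

    ``skin_contraction`` is in mm; every other length is in cm.
    ``vmat_max_length=None`` derives the limit from the machine constants.
    """

    skin_contraction: float = 3.0
    mlc_travel_limit: float = 14.5
    field_margin_per_side: float = 0.5
    ofz_halfwidth: float = 2.5
    appa_allowed_lengths: tuple[float, ...] = (25.0, 30.0, 35.0)
    feet_margin_min: float = 5.0
    appa_width_limit: float = 35.0
    vmat_max_length: float | None = None
    # The last full VMAT block ends just below the top of the legs, so the
    # AP/PA fields only cover legs and feet (within the width eligibility);
    # set False to force every VMAT block to end at or above legs_top.
    allow_vmat_below_legs_top: bool = True

    def __post_init__(self) -> None:
        if list(self.appa_allowed_lengths) != sorted(self.appa_allowed_lengths):
            raise ValueError("appa_allowed_lengths must be sorted ascending")
        if self.ofz_halfwidth <= 0:
            raise ValueError("ofz_halfwidth must be positive")

    @property
    def limits(self) -> VmatLimits:
        return compute_vmat_limit(
            self.mlc_travel_limit, self.field_margin_per_side, 2.0 * self.ofz_halfwidth
        )

    @property
    def vmat_length_cm(self) -> float:
        return self.vmat_max_length if self.vmat_max_length is not None else self.limits.subtarget_limit

    @property
    def ofz_halfwidth_mm(self) -> float:
        return self.ofz_halfwidth * 10.0

    @property
    def junction_width_mm(self) -> float:
        return 2.0 * self.ofz_halfwidth_mm


@dataclass(frozen=True)
class SubTarget:
    """One longitudinal slab of the PTV planned around its own isocenter."""

    index: int  # ordinal from the head, 1-based
    kind: str  # "VMAT" | "APPA"
    z_interval: tuple[float, float]  # mm, [inferior, superior)
    opt_interval: tuple[float, float]  # expanded by the OFZ on interior ends
    isocenter: tuple[float, float, float]  # mm

    @property
    def length_mm(self) -> float:
        return self.z_interval[1] - self.z_interval[0]

    def __post_init__(self) -> None:
        if self.kind not in ("VMAT", "APPA"):
            raise ValueError(f"unknown sub-target kind {self.kind!r}")
        if self.length_mm <= 0:
            raise ValueError("sub-target interval must have positive length")


@dataclass
class SubTargetSet:
    """Ordered head-to-feet partition with junction points and the origin."""

    subtargets: list[SubTarget]
    junction_points: list[tuple[float, float, float]]
    origin_point: tuple[float, float, float]
    ptv_z_extent: tuple[float, float]  # mm, [inferior, superior]
    params: SegmentationParams = field(default_factory=SegmentationParams)

    @property
    def iso_xy(self) -> tuple[float, float]:
        return self.origin_point[0], self.origin_point[1]

    @property
    def n_appa(self) -> int:
        return sum(1 for s in self.subtargets if s.kind == "APPA")

    def junction_z(self) -> list[float]:
        return [p[2] for p in self.junction_points]

    def junction_intervals(self) -> list[tuple[float, float]]:
        h = self.params.ofz_halfwidth_mm
        return [(z - h, z + h) for z in self.junction_z()]

    def validate(self) -> None:
        """Partition invariants: contiguity, OFZ overlaps, collinearity,
        equal AP/PA lengths, feet margin."""
        sts = self.subtargets
        if not sts:
            raise ValueError("empty sub-target set")
        h = self.params.ofz_halfwidth_mm
        tol = 1e-6
        for a, b in zip(sts, sts[1:]):
            if abs(a.z_interval[0] - b.z_interval[1]) > tol:
                raise ValueError(
                    f"sub-targets {a.index} and {b.index} do not tile contiguously"
                )
            ov = a.opt_interval[0], b.opt_interval[1]
            if abs((ov[1] - ov[0]) - 2.0 * h) > tol:
                raise ValueError(
                    f"opt intervals of {a.index}/{b.index} overlap by "
                    f"{ov[1] - ov[0]} mm, expected {2 * h}"
                )
        kinds = [s.kind for s in sts]
        if "APPA" in kinds:
            first = kinds.index("APPA")
            if any(k != "APPA" for k in kinds[first:]):
                raise ValueError("AP/PA sub-targets must form the most inferior run")
            lens = {round(s.length_mm, 3) for s in sts if s.kind == "APPA"}
            if len(lens) > 1:
                raise ValueError(f"AP/PA sub-targets have unequal lengths: {lens}")
            if sts[-1].z_interval[0] > self.ptv_z_extent[0] - 10.0 * self.params.feet_margin_min + tol:
                raise ValueError("AP/PA coverage does not leave the required feet margin")
        top, bottom = sts[0].z_interval[1], sts[-1].z_interval[0]
        if top < self.ptv_z_extent[1] - tol or bottom > self.ptv_z_extent[0] + tol:
            raise ValueError("sub-target intervals do not cover the PTV z extent")
        pts = [s.isocenter for s in sts] + list(self.junction_points)
        for p in pts:
            if abs(p[0] - self.origin_point[0]) > tol or abs(p[1] - self.origin_point[1]) > tol:
                raise ValueError("isocenters and junction points are not collinear")

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "origin_point_mm": list(self.origin_point),
            "ptv_z_extent_mm": list(self.ptv_z_extent),
            "junction_points_mm": [list(p) for p in self.junction_points],
            "subtargets": [
                {
                    "index": s.index,
                    "kind": s.kind,
                    "z_interval_mm": list(s.z_interval),
                    "opt_interval_mm": list(s.opt_interval),
                    "isocenter_mm": list(s.isocenter),
                }
                for s in self.subtargets
            ],
            "params": {
                "skin_contraction": self.params.skin_contraction,
                "ofz_halfwidth": self.params.ofz_halfwidth,
                "appa_allowed_lengths": list(self.params.appa_allowed_lengths),
                "feet_margin_min": self.params.feet_margin_min,
                "mlc_travel_limit": self.params.mlc_travel_limit,
                "field_margin_per_side": self.params.field_margin_per_side,
                "appa_width_limit": self.params.appa_width_limit,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "SubTargetSet":
        params = SegmentationParams(
            skin_contraction=d["params"]["skin_contraction"],
            ofz_halfwidth=d["params"]["ofz_halfwidth"],
            appa_allowed_lengths=tuple(d["params"]["appa_allowed_lengths"]),
            feet_margin_min=d["params"]["feet_margin_min"],
            mlc_travel_limit=d["params"]["mlc_travel_limit"],
            field_margin_per_side=d["params"]["field_margin_per_side"],
            appa_width_limit=d["params"]["appa_width_limit"],
        )
        sts = [
            SubTarget(
                s["index"], s["kind"],
                tuple(s["z_interval_mm"]), tuple(s["opt_interval_mm"]),
                tuple(s["isocenter_mm"]),
            )
            for s in d["subtargets"]
        ]
        return cls(
            sts,
            [tuple(p) for p in d["junction_points_mm"]],
            tuple(d["origin_point_mm"]),
            tuple(d["ptv_z_extent_mm"]),
            params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SubTargetSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_ptv(structures: StructureSet, params: SegmentationParams) -> np.ndarray:
    """PTV mask: body contracted from the skin, minus lungs and kidneys."""
    structures.require("body", "lungs", "kidneys")
    body = structures.masks["body"]
    if params.skin_contraction > 0:
        dist = ndimage.distance_transform_edt(body, sampling=structures.grid.spacing)
        shell = dist >= params.skin_contraction
    else:
        shell = body
    ptv = shell & ~structures.masks["lungs"] & ~structures.masks["kidneys"]
    if not ptv.any():
        raise ValueError("PTV is empty after contraction and organ exclusion")
    return ptv


def appa_length_lookup(
    remaining_length: float, params: SegmentationParams
) -> tuple[float, int]:
    """Choose the AP/PA sub-target length (cm) and count for a remaining
    PTV length (cm below the last VMAT sub-target).

    Covers the remainder plus the required feet margin with as few
    isocenters as possible, then with the shortest allowed length.
    """
    if remaining_length <= 0:
        raise ValueError("remaining_length must be positive")
    need = remaining_length + params.feet_margin_min
    count = 1
    while True:
        feasible = [l for l in params.appa_allowed_lengths if count * l >= need - 1e-9]
        if feasible:
            return min(feasible), count
        count += 1


def _interval_center(iv: tuple[float, float]) -> float:
    return 0.5 * (iv[0] + iv[1])


def _assemble(
    boundaries_vmat: list[float],
    ptv_top: float,
    ptv_bottom: float,
    iso_xy: tuple[float, float],
    params: SegmentationParams,
    appa_start: float | None,
) -> SubTargetSet:
    """Build a SubTargetSet from the inferior boundaries of the VMAT
    sub-targets (mm, head-to-feet order) and optionally the AP/PA stack
    starting at ``appa_start``."""
    ofz = params.ofz_halfwidth_mm
    intervals: list[tuple[float, float, str]] = []
    top = ptv_top
    for b in boundaries_vmat:
        intervals.append((b, top, "VMAT"))
        top = b
    if appa_start is not None:
        remaining_cm = (appa_start - ptv_bottom) / 10.0
        length_cm, count = appa_length_lookup(remaining_cm, params)
        length = length_cm * 10.0
        b = appa_start
        for _ in range(count):
            intervals.append((b - length, b, "APPA"))
            b -= length

    sts: list[SubTarget] = []
    n = len(intervals)
    for i, (lo, hi, kind) in enumerate(intervals):
        opt_lo = lo - ofz if i < n - 1 else lo
        opt_hi = hi + ofz if i > 0 else hi
        ctr = _interval_center((lo, hi))
        sts.append(
            SubTarget(
                index=i + 1,
                kind=kind,
                z_interval=(lo, hi),
                opt_interval=(opt_lo, opt_hi),
                isocenter=(iso_xy[0], iso_xy[1], ctr),
            )
        )
    junctions = [
        (iso_xy[0], iso_xy[1], sts[i].z_interval[0]) for i in range(n - 1)
    ]
    out = SubTargetSet(
        sts,
        junctions,
        (iso_xy[0], iso_xy[1], 0.0),
        (ptv_bottom, ptv_top),
        params,
    )
    out.validate()
    return out


def _ptv_geometry(
    ptv: np.ndarray, grid: Grid
) -> tuple[float, float, tuple[float, float]]:
    """(ptv_top, ptv_bottom) outer z extent in mm and the shared iso (x, y)
    from the pelvis-level PTV centroid, rounded to 1 mm."""
    zc = grid.axis_coords(2)
    any_z = ptv.any(axis=(0, 1))
    zs = np.nonzero(any_z)[0]
    if zs.size == 0:
        raise ValueError("PTV mask is empty")
    h = grid.spacing[2] / 2.0
    ptv_bottom, ptv_top = float(zc[zs[0]] - h), float(zc[zs[-1]] + h)
    pelvis = np.abs(zc) <= 25.0
    sel = ptv[:, :, pelvis]
    if not sel.any():
        sel = ptv
    ix, iy, _ = np.nonzero(sel)
    x = round(float(np.mean(grid.axis_coords(0)[ix])), 0)
    y = round(float(np.mean(grid.axis_coords(1)[iy])), 0)
    return ptv_top, ptv_bottom, (x, y)


def divide_ptv(
    ptv: np.ndarray,
    grid: Grid,
    landmarks: dict[str, float],
    params: SegmentationParams | None = None,
) -> SubTargetSet:
    """Divide the PTV into VMAT and AP/PA sub-targets.

    The first VMAT sub-target runs from the bottom of the neck to the top
    of the head; fixed-length VMAT blocks follow inferiorly while a full
    block still ends at or above the top of the legs; the AP/PA look-up
    covers the remainder down past the feet.
    """
    params = params or SegmentationParams()
    for name in ("head_top", "neck_bottom", "legs_top", "feet_bottom"):
        if name not in landmarks:
            raise ValueError(f"missing landmark {name!r}")
    ptv_top, ptv_bottom, iso_xy = _ptv_geometry(ptv, grid)
    neck_bottom = landmarks["neck_bottom"]
    legs_top = landmarks["legs_top"]
    if not (ptv_bottom < neck_bottom < ptv_top):
        raise ValueError("neck_bottom landmark is inconsistent with the PTV extent")

    head_len_cm = (ptv_top - neck_bottom) / 10.0
    if head_len_cm + params.ofz_halfwidth > params.limits.opt_limit:
        raise ValueError(
            f"head sub-target of {head_len_cm:.1f} cm exceeds the optimization "
            f"length limit {params.limits.opt_limit} cm; review the phantom spec"
        )

    L = params.vmat_length_cm * 10.0
    boundaries = [neck_bottom]
    b = neck_bottom
    appa_start: float | None = None
    while True:
        if b - ptv_bottom <= 1e-9:
            break  # PTV exhausted by VMAT blocks
        if params.allow_vmat_below_legs_top:
            add_block = b > legs_top + 1e-9  # last block crosses legs_top
        else:
            add_block = b - L >= legs_top - 1e-9  # blocks stay above legs_top
        if add_block:
            nxt = b - L
            if nxt - ptv_bottom <= 1e-9:
                boundaries.append(ptv_bottom)  # trim the last block to the PTV
                b = ptv_bottom
            else:
                boundaries.append(nxt)
                b = nxt
        else:
            appa_start = b
            break
    return _assemble(boundaries, ptv_top, ptv_bottom, iso_xy, params, appa_start)


def pediatric_adjust(
    sts: SubTargetSet,
    structures: StructureSet,
    is_pediatric: bool = True,
) -> SubTargetSet:
    """Shorten thoracic/abdominal VMAT sub-targets so that one junction's
    feathering overlap lies entirely in the lung-kidney longitudinal gap.

    Lengths are only ever reduced; sub-targets below the moved boundary
    shift superiorly, and the AP/PA stack is rebuilt for the enlarged
    remainder.  A no-op for adults or when a junction already fits.
    """
    if not is_pediatric:
        return sts
    structures.require("lungs", "kidneys")
    lung_bottom, _ = structures.mask_z_extent("lungs")
    _, kid_top = structures.mask_z_extent("kidneys")
    gap = lung_bottom - kid_top
    h = sts.params.ofz_halfwidth_mm
    if gap < 2.0 * h:
        raise ValueError(
            f"lung-kidney gap of {gap / 10.0:.1f} cm cannot hold the "
            f"{2 * h / 10.0:.0f} cm junction overlap"
        )
    lo_ok, hi_ok = kid_top + h, lung_bottom - h

    vmat = [s for s in sts.subtargets if s.kind == "VMAT"]
    if len(vmat) < 2:
        raise ValueError("pediatric adjustment needs at least two VMAT sub-targets")
    # boundaries below the head sub-target (inferior edge of each VMAT block)
    bounds = [s.z_interval[0] for s in vmat]
    if any(lo_ok - 1e-9 <= b <= hi_ok + 1e-9 for b in bounds):
        return sts  # a junction already sits in the gap

    candidates = [(i, b) for i, b in enumerate(bounds) if b < lo_ok]
    feasible = []
    for i, b in candidates:
        delta = lo_ok - b
        n_above = i + 1 - 1  # VMAT blocks between the head block and this boundary
        if i == 0:
            continue  # cannot shorten the head sub-target definition
        per = delta / n_above
        lengths = [vmat[k].length_mm - per for k in range(1, i + 1)]
        if all(l > 2.0 * h + 1e-9 for l in lengths):
            feasible.append((delta, i, per))
    if not feasible:
        raise ValueError(
            "no VMAT boundary can be moved into the lung-kidney gap by "
            "shortening sub-targets"
        )
    delta, i, per = min(feasible)

    ptv_bottom, ptv_top = sts.ptv_z_extent
    new_bounds = []
    shift = 0.0
    for k, s in enumerate(vmat):
        if k == 0:
            new_bounds.append(s.z_interval[0])  # head boundary unchanged
        elif 1 <= k <= i:
            shift += per
            new_bounds.append(s.z_interval[0] + shift)
        else:
            new_bounds.append(s.z_interval[0] + shift)
    appa_start = new_bounds[-1] if sts.n_appa > 0 else None
    out = _assemble(
        new_bounds, ptv_top, ptv_bottom, sts.iso_xy, sts.params, appa_start
    )
    # containment check: the moved junction overlap lies inside the gap
    jz = new_bounds[i]
    if not (kid_top - 1e-6 <= jz - h and jz + h <= lung_bottom + 1e-6):
        raise ValueError("junction relocation failed to land in the lung-kidney gap")
    return out


def large_patient_adjust(
    sts: SubTargetSet,
    arm_extent_cm: float,
    width_threshold_cm: float = 40.0,
    reduction_cm: float = 2.0,
) -> SubTargetSet:
    """Shorten trunk VMAT sub-targets by 1-2 cm when the lateral extent
    (arms included) exceeds the width threshold, then re-tile."""
    if not (1.0 <= reduction_cm <= 2.0):
        raise ValueError("reduction must be 1-2 cm")
    if arm_extent_cm <= width_threshold_cm:
        return sts
    vmat = [s for s in sts.subtargets if s.kind == "VMAT"]
    ptv_bottom, ptv_top = sts.ptv_z_extent
    red = reduction_cm * 10.0
    new_bounds = []
    shift = 0.0
    for k, s in enumerate(vmat):
        if k == 0:
            new_bounds.append(s.z_interval[0])
        else:
            shift += red
            new_bounds.append(s.z_interval[0] + shift)
    appa_start = new_bounds[-1] if sts.n_appa > 0 else None
    if appa_start is None and new_bounds[-1] > ptv_bottom + 1e-9:
        appa_start = new_bounds[-1]
    return _assemble(new_bounds, ptv_top, ptv_bottom, sts.iso_xy, sts.params, appa_start)
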