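"""Whole-body plan conversion to head-first / feet-first delivery plans.

The whole-body plan is planned on the head-first (SHF) frame.  Beams with
isocenters superior to the pelvis origin point are delivered head-first;
beams inferior to it are delivered feet-first (SFF) after the inversion
transform: the collimator rotates by 180 degrees, the gantry angle is
mirrored left-right (g -> 360 - g), and the isocenter is re-expressed in
the feet-first frame (x and z negated about the origin point — a
180-degree rotation about the vertical axis, the physical "rotate series"
operation).  Monitor units, energy, and segment apertures are untouched;
the combination of the mirrored gantry and the rotated collimator maps the
beam's-eye-view basis exactly onto its rotated self, so the delivered dose
is unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dose_model import Beam, PhysicsConstants, compute_beam_dose, density_from_hu
from .planning import TBIPlan
from .volumes import DoseGrid, ImageVolume

__all__ = ["DeliveryPlan", "invert_beam_to_sff", "split_plan", "verify_equivalence"]


@dataclass
class DeliveryPlan:
    """Beams of one delivery orientation plus the planned table moves."""

    orientation: str  # "SHF" | "SFF"
    beams: list[Beam]
    origin_point: tuple[float, float, float]
    provenance: str = ""
    table_shifts_mm: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation not in ("SHF", "SFF"):
            raise ValueError("orientation must be 'SHF' or 'SFF'")

    def total_mu(self) -> float:
        return float(sum(b.mu for b in self.beams))

    def to_dict(self) -> dict:
        from .planning import _jsonable

        return {
            "orientation": self.orientation,
            "origin_point_mm": list(self.origin_point),
            "provenance": self.provenance,
            "table_shifts_mm": self.table_shifts_mm,
            "beams": [
                {
                    "label": b.label,
                    "technique": b.technique,
                    "isocenter_mm": list(b.isocenter),
                    "gantry_deg": b.gantry,
                    "collimator_deg": b.collimator,
                    "energy_mv": b.energy,
                    "sad_cm": b.sad_cm,
                    "mu": b.mu,
                    "mu_rate": b.mu_rate,
                    "segments": [
                        {"aperture_cm": list(s.aperture), "weight": s.relative_weight}
                        for s in b.segments
                    ],
                    "meta": _jsonable(b.meta),
                }
                for b in self.beams
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _mirror_z(z: float, oz: float) -> float:
    return 2.0 * oz - z


def invert_beam_to_sff(
    beam: Beam, origin_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
) -> Beam:
    """Invert a whole-body-frame beam for feet-first delivery (involution)."""
    ox, _, oz = origin_point
    iso = beam.isocenter
    new_iso = (2.0 * ox - iso[0], iso[1], _mirror_z(iso[2], oz))
    meta = dict(beam.meta)
    if beam.technique == "vmat_arc_surrogate":
        lo, hi = meta["z_interval"]
        meta["z_interval"] = (_mirror_z(hi, oz), _mirror_z(lo, oz))
        lo, hi = meta["opt_interval"]
        meta["opt_interval"] = (_mirror_z(hi, oz), _mirror_z(lo, oz))
        flip_end = {"inferior": "superior", "superior": "inferior"}
        meta["ramps"] = [
            (_mirror_z(float(jz), oz), flip_end[end]) for jz, end in meta.get("ramps", [])
        ]
        prof = meta.get("neighbor_profile")
        if prof is not None:
            meta["neighbor_profile"] = {
                "z": [_mirror_z(float(z), oz) for z in prof["z"]],
                "gy": list(prof["gy"]),
            }
    return replace(
        beam,
        gantry=(360.0 - beam.gantry) % 360.0,
        collimator=(beam.collimator + 180.0) % 360.0,
        isocenter=new_iso,
        segments=[replace(s) for s in beam.segments],
        meta=meta,
    )


def _table_shifts(beams: list[Beam]) -> list[float]:
    zs = sorted({round(b.isocenter[2], 6) for b in beams}, reverse=True)
    return [zs[i] - zs[i + 1] for i in range(len(zs) - 1)]


def split_plan(
    plan: TBIPlan, origin_point: tuple[float, float, float] | None = None
) -> tuple[DeliveryPlan, DeliveryPlan]:
    """Partition the whole-body plan into SHF and SFF delivery plans.

    Beams with isocenters superior to the origin point stay head-first;
    inferior beams are inverted to the feet-first frame.  An isocenter
    exactly at the origin z is an error (a silent choice would risk
    double delivery)."""
    origin = origin_point or plan.origin_point
    oz = origin[2]
    shf_beams, sff_beams = [], []
    for b in plan.beams:
        if abs(b.isocenter[2] - oz) < 1e-9:
            raise ValueError(
                f"beam {b.label!r} isocenter lies exactly at the origin z; "
                "move the origin or the isocenter to break the tie"
            )
        if b.isocenter[2] > oz:
            shf_beams.append(replace(b, segments=[replace(s) for s in b.segments]))
        else:
            sff_beams.append(invert_beam_to_sff(b, origin))
    if not sff_beams or not shf_beams:
        warnings.warn("one delivery orientation holds no beams", stacklevel=2)
    prov = f"whole-body plan, rx {plan.rx_gy} Gy in {plan.fractions} fx"
    return (
        DeliveryPlan("SHF", shf_beams, origin, prov, _table_shifts(shf_beams)),
        DeliveryPlan("SFF", sff_beams, origin, prov, _table_shifts(sff_beams)),
    )


def _flip_volume(ct: ImageVolume, center: tuple[float, float]) -> ImageVolume:
    """The CT as seen in the feet-first frame (exact axis flip)."""
    return ImageVolume(
        ct.grid.flipped_xz(center), ct.values[::-1, :, ::-1].copy(), "HFS"
    )


def verify_equivalence(
    whole_dose: DoseGrid,
    shf: DeliveryPlan,
    sff: DeliveryPlan,
    ct: ImageVolume,
    constants: PhysicsConstants | None = None,
    tol: float = 1e-6,
) -> dict:
    """Recompute SHF beams in the SHF frame and SFF beams in the SFF frame,
    map both into the whole-body frame, sum, and compare voxelwise."""
    constants = constants or PhysicsConstants()
    grid = whole_dose.grid
    if tuple(shf.origin_point) != tuple(sff.origin_point):
        raise ValueError("frame mapping failure: delivery plans disagree on the origin point")
    ox, _, oz = shf.origin_point
    center = (ox, oz)

    total = DoseGrid.zeros(grid)
    density = density_from_hu(ct.values, constants)
    for b in shf.beams:
        total = total + compute_beam_dose(b, ct, constants, grid=grid, density=density)

    if sff.beams:
        ct_f = _flip_volume(ct, center)
        grid_f = grid.flipped_xz(center)
        density_f = density[::-1, :, ::-1].copy()
        sff_dose = DoseGrid.zeros(grid_f)
        for b in sff.beams:
            sff_dose = sff_dose + compute_beam_dose(
                b, ct_f, constants, grid=grid_f, density=density_f
            )
        back = sff_dose.flipped_xz(center)
        if not back.grid.same_geometry(grid):
            raise ValueError("frame mapping failure: flipped dose grid mismatch")
        total = total + back

    diff = np.abs(total.values - whole_dose.values)
    max_diff = float(diff.max()) if diff.size else 0.0
    loc = np.unravel_index(int(np.argmax(diff)), diff.shape) if diff.size else (0, 0, 0)
    return {
        "max_abs_diff_gy": max_diff,
        "tolerance_gy": tol,
        "passed": bool(max_diff <= tol),
        "worst_voxel_index": [int(i) for i in loc],
        "mu_whole": None,
        "mu_delivery": shf.total_mu() + sff.total_mu(),
    }
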