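"""Whole-body plan assembly: feathered AP/PA beams, VMAT surrogate doses,
the classic extended-SSD comparator, and plan-level metrics.

The VMAT optimizer itself is out of scope; each VMAT sub-target is carried
as a surrogate pseudo-beam whose "dose" is the idealized distribution the
junction base dose forces an optimizer toward: the prescription inside the
optimization interval, complemented across each junction so that adjacent
contributions sum to the prescription.  At VMAT-VMAT junctions the base is
the linear ramp idealizing the 5-level step wedge (the staircase bin
midpoints are collinear); at the VMAT/AP-PA junction the base is the
actually delivered AP/PA column profile, frozen into the pseudo-beam so a
delivery plan recomputes identically on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .dose_model import (
    Beam,
    BeamSegment,
    Block,
    PhysicsConstants,
    beam_basis,
    compute_beam_dose,
    compute_dvh,
    default_dose_grid,
    density_from_hu,
    dose_at_points,
    lung_dose_rate,
    make_feathered_appa,
    optimize_segment_weights,
    vmat_surrogate_dose,
)
from .segmentation import SubTarget, SubTargetSet
from .volumes import DoseGrid, Grid, ImageVolume, StructureSet, resample_to_grid

__all__ = [
    "TBIPlan",
    "build_whole_body_plan",
    "surrogate_beam_dose",
    "linear_junction_base",
    "recreate_classic_appa",
    "plan_metrics",
]


def linear_junction_base(
    zc: np.ndarray, junction_z: float, end: str, rx: float, width_mm: float = 50.0
) -> np.ndarray:
    """Base-dose z profile forcing a linear falloff across a junction.

    ``end`` names the sub-target end the junction sits on: for the
    ``"inferior"`` end the wedge ascends toward the inferior neighbour, so
    the complemented dose falls off downward (and mirrored for
    ``"superior"``)."""
    h = width_mm / 2.0
    if end == "inferior":
        f = (junction_z + h - zc) / width_mm
    elif end == "superior":
        f = (zc - (junction_z - h)) / width_mm
    else:
        raise ValueError("end must be 'inferior' or 'superior'")
    return rx * np.clip(f, 0.0, 1.0)


def _surrogate_meta_to_subtarget(meta: dict, beam: Beam) -> SubTarget:
    return SubTarget(
        index=int(meta["subtarget_index"]),
        kind="VMAT",
        z_interval=tuple(meta["z_interval"]),
        opt_interval=tuple(meta["opt_interval"]),
        isocenter=tuple(beam.isocenter),
    )


def surrogate_beam_dose(
    beam: Beam,
    ct: ImageVolume,
    grid: Grid | None = None,
    constants: PhysicsConstants | None = None,
) -> DoseGrid:
    """Reconstruct the surrogate dose of a VMAT pseudo-beam from its frozen
    metadata (ramps, neighbour profile, lung sparing factor)."""
    constants = constants or PhysicsConstants()
    grid = grid or default_dose_grid(ct)
    meta = beam.meta
    rx = float(meta["rx"])
    st = _surrogate_meta_to_subtarget(meta, beam)
    zc = grid.axis_coords(2)
    base_z = np.zeros(zc.shape, dtype=np.float64)
    for junction_z, end in meta.get("ramps", []):
        base_z += linear_junction_base(zc, float(junction_z), end, rx, float(meta.get("junction_width_mm", 50.0)))
    prof = meta.get("neighbor_profile")
    if prof is not None:
        pz = np.asarray(prof["z"], dtype=float)
        pv = np.asarray(prof["gy"], dtype=float)
        order = np.argsort(pz)
        base_z += np.interp(zc, pz[order], pv[order], left=0.0, right=0.0)
    base_z = np.minimum(base_z, rx)
    base = DoseGrid(grid, np.broadcast_to(base_z, grid.shape).copy())

    lung_mask = None
    lung_scale = meta.get("lung_scale")
    if lung_scale is not None:
        density = density_from_hu(ct.values, constants)
        rho = resample_to_grid(ImageVolume(ct.grid, density), grid, order=0, cval=0.0).values
        lung_mask = (rho > 0.05) & (rho < 0.6)
    return vmat_surrogate_dose(
        st, base, rx, ct, grid=grid, constants=constants,
        lung_mask=lung_mask, lung_scale=lung_scale,
    )


@dataclass
class TBIPlan:
    """A whole-body plan: beams grouped by isocenter plus frozen dose grids."""

    subtargets: SubTargetSet
    beams: list[Beam]
    iso_doses: dict[int, DoseGrid]  # sub-target index -> dose contribution
    rx_gy: float
    fractions: int
    grid: Grid
    constants: PhysicsConstants = field(default_factory=PhysicsConstants)
    lung_subtarget_index: int | None = None

    @property
    def rx_per_fraction_gy(self) -> float:
        return self.rx_gy / self.fractions

    @property
    def origin_point(self) -> tuple[float, float, float]:
        return self.subtargets.origin_point

    def total_dose(self) -> DoseGrid:
        out = DoseGrid.zeros(self.grid)
        for dg in self.iso_doses.values():
            out = out + dg
        return out

    def beams_at(self, subtarget_index: int) -> list[Beam]:
        return [b for b in self.beams if b.meta.get("subtarget_index") == subtarget_index]

    def total_mu(self) -> float:
        return float(sum(b.mu for b in self.beams))

    def isocenters(self) -> dict[int, tuple[float, float, float]]:
        return {s.index: s.isocenter for s in self.subtargets.subtargets}

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def seg_d(s: BeamSegment) -> dict:
            return {"aperture_cm": list(s.aperture), "weight": s.relative_weight}

        return {
            "rx_gy": self.rx_gy,
            "fractions": self.fractions,
            "lung_subtarget_index": self.lung_subtarget_index,
            "subtargets": self.subtargets.to_dict(),
            "beams": [
                {
                    "label": b.label,
                    "technique": b.technique,
                    "isocenter_mm": list(b.isocenter),
                    "gantry_deg": b.gantry,
                    "collimator_deg": b.collimator,
                    "couch_deg": b.couch,
                    "energy_mv": b.energy,
                    "sad_cm": b.sad_cm,
                    "mu": b.mu,
                    "mu_rate": b.mu_rate,
                    "segments": [seg_d(s) for s in b.segments],
                    "meta": _jsonable(b.meta),
                }
                for b in self.beams
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, dict):
            out[k] = _jsonable(v)
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out


def _resample_mask(mask: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    v = resample_to_grid(ImageVolume(src, mask.astype(np.float32)), dst, order=0, cval=0.0)
    return v.values > 0.5


def build_whole_body_plan(
    ct: ImageVolume,
    structures: StructureSet,
    subtargets: SubTargetSet,
    ptv: np.ndarray,
    rx_gy: float = 13.2,
    fractions: int = 8,
    constants: PhysicsConstants | None = None,
    grid: Grid | None = None,
    lung_goal_gy: float | None = None,
    modulation_factor: float = 10.0,
) -> TBIPlan:
    """Assemble the whole-body plan on the 5 mm dose grid.

    AP/PA sub-targets get feathered 6 MV beam pairs whose segment weights
    are jointly optimized (NNLS) to the prescription over the AP/PA region
    plus the complementary ramp across the junction to the VMAT region;
    VMAT sub-targets get surrogate pseudo-beams (see module docstring).
    The lung-isocenter beams run at 200 MU/min, all others at 600 MU/min.
    """
    constants = constants or PhysicsConstants()
    grid = grid or default_dose_grid(ct)
    params = subtargets.params
    sts = subtargets.subtargets
    if lung_goal_gy is None:
        lung_goal_gy = 10.0
    rx = rx_gy

    ptv_d = _resample_mask(ptv, structures.grid, grid)
    body_d = _resample_mask(structures.masks["body"], structures.grid, grid)
    density = density_from_hu(ct.values, constants)
    zc = grid.axis_coords(2)

    lungs_lo, lungs_hi = structures.mask_z_extent("lungs")
    lung_mid = 0.5 * (lungs_lo + lungs_hi)
    lung_index = None
    for s in sts:
        if s.kind == "VMAT" and s.z_interval[0] <= lung_mid < s.z_interval[1]:
            lung_index = s.index
            break

    beams: list[Beam] = []
    iso_doses: dict[int, DoseGrid] = {}

    # ---- AP/PA sub-targets -------------------------------------------------
    appa_sts = [s for s in sts if s.kind == "APPA"]
    appa_total = None
    if appa_sts:
        from .dose_model import BeamKernel

        raw_beams: list[Beam] = []
        for s in appa_sts:
            is_last = s.index == sts[-1].index
            ap, pa = make_feathered_appa(s, params, is_last=is_last)
            raw_beams.extend([ap, pa])
        kernels = [
            BeamKernel(b, ct, constants, grid=grid, density=density) for b in raw_beams
        ]
        # uniform target: PTV inside the AP/PA region, below the VMAT junction
        top_junction = appa_sts[0].z_interval[1]
        h = params.ofz_halfwidth_mm
        uniform = ptv_d & (zc[None, None, :] < top_junction - h)
        ramp_mask = body_d & (zc[None, None, :] >= top_junction - h) & (
            zc[None, None, :] <= top_junction + h
        )
        # the AP/PA contribution must fall off toward the VMAT neighbour;
        # targeting the ramp spanning one feathering step beyond the
        # junction puts the three staircase levels at 1, 2/3, 1/3, 0 (equal
        # steps -> least sensitivity to longitudinal shifts)
        ramp_vals = np.broadcast_to(
            linear_junction_base(zc, top_junction, "inferior", rx, 3.0 * h)[None, None, :],
            grid.shape,
        )
        if not uniform.any():
            uniform = ptv_d & ramp_mask
        raw_beams, _ = optimize_segment_weights(
            raw_beams, uniform, ct, constants, rx=rx, grid=grid,
            ramp_target=(ramp_mask, ramp_vals), kernels=kernels,
        )
        for s in appa_sts:
            dg = DoseGrid.zeros(grid)
            pair = []
            for b, k in zip(raw_beams, kernels):
                if b.meta.get("subtarget_index") != s.index:
                    continue
                pair.append(b)
                if b.mu > 0:
                    dg = dg + k.dose(b)
            iso_doses[s.index] = dg
            beams.extend(pair)
        appa_total = DoseGrid.zeros(grid)
        for s in appa_sts:
            appa_total = appa_total + iso_doses[s.index]

    # ---- VMAT sub-targets --------------------------------------------------
    iso_x, iso_y = subtargets.iso_xy
    for i, s in enumerate(sts):
        if s.kind != "VMAT":
            continue
        ramps = []
        neighbor_profile = None
        if i > 0:
            ramps.append((s.z_interval[1], "superior"))
        if i < len(sts) - 1:
            below = sts[i + 1]
            if below.kind == "VMAT":
                ramps.append((s.z_interval[0], "inferior"))
            else:
                z_col, gy_col = appa_total.column(iso_x, iso_y)
                gy_col = np.minimum(gy_col, rx)
                keep = gy_col > 1e-9
                neighbor_profile = {
                    "z": z_col[keep].tolist(),
                    "gy": gy_col[keep].tolist(),
                }
        mu_rate = 200.0 if s.index == lung_index else 600.0
        lung_scale = (lung_goal_gy / rx) if s.index == lung_index else None
        pseudo = Beam(
            isocenter=s.isocenter,
            gantry=0.0,
            collimator=90.0,
            energy=6,
            mu=vmat_iso_mu(rx, fractions, modulation_factor),
            mu_rate=mu_rate,
            segments=[
                BeamSegment(
                    (
                        (s.opt_interval[0] - s.isocenter[2]) / 10.0,
                        (s.opt_interval[1] - s.isocenter[2]) / 10.0,
                        -20.0,
                        20.0,
                    ),
                    1.0,
                )
            ],
            technique="vmat_arc_surrogate",
            label=f"VMAT{s.index}",
            meta={
                "subtarget_index": s.index,
                "z_interval": tuple(s.z_interval),
                "opt_interval": tuple(s.opt_interval),
                "rx": rx,
                "ramps": ramps,
                "junction_width_mm": 2.0 * params.ofz_halfwidth_mm,
                "neighbor_profile": neighbor_profile,
                "lung_scale": lung_scale,
            },
        )
        # split-arc constraint: the optimization interval must fit the field
        opt_len_cm = (s.opt_interval[1] - s.opt_interval[0]) / 10.0
        if opt_len_cm > params.limits.field_length + 1e-9:
            raise ValueError(
                f"VMAT sub-target {s.index}: optimization interval of "
                f"{opt_len_cm:.1f} cm exceeds the split-arc field length "
                f"{params.limits.field_length} cm"
            )
        iso_doses[s.index] = surrogate_beam_dose(pseudo, ct, grid=grid, constants=constants)
        beams.append(pseudo)

    return TBIPlan(
        subtargets=subtargets,
        beams=beams,
        iso_doses=iso_doses,
        rx_gy=rx,
        fractions=fractions,
        grid=grid,
        constants=constants,
        lung_subtarget_index=lung_index,
    )


def vmat_iso_mu(rx_gy: float, fractions: int, modulation_factor: float) -> float:
    """Per-isocenter VMAT monitor units per fraction: the per-fraction
    prescription in cGy times an engineering modulation factor."""
    return (rx_gy / fractions) * 100.0 * modulation_factor


def plan_metrics(
    plan: TBIPlan,
    structures: StructureSet,
    ptv: np.ndarray,
) -> dict:
    """DVH metrics for PTV/lungs/kidneys plus the lung dose rate."""
    dose = plan.total_dose()
    out: dict = {}
    masks = {"ptv": ptv, "lungs": structures.masks["lungs"], "kidneys": structures.masks["kidneys"]}
    for name, m in masks.items():
        md = _resample_mask(m, structures.grid, plan.grid)
        if md.any():
            out[name] = compute_dvh(dose, md, plan.rx_gy)
    if plan.lung_subtarget_index is not None:
        lung_mask_d = _resample_mask(structures.masks["lungs"], structures.grid, plan.grid)
        lung_beams = plan.beams_at(plan.lung_subtarget_index)
        lung_dose_fx = float(
            plan.iso_doses[plan.lung_subtarget_index].values[lung_mask_d].mean()
        ) / plan.fractions
        out["lung_dose_rate_cgy_min"] = lung_dose_rate(lung_beams, lung_dose_fx)
    return out


# --------------------------------------------------------------------------
# Classic extended-SSD AP/PA comparator
# --------------------------------------------------------------------------


def _project_mask_bev(
    mask: np.ndarray,
    grid: Grid,
    beam: Beam,
    pixel_mm: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project a voxel mask into the beam's-eye view at the isocenter plane."""
    idx = np.nonzero(mask)
    if idx[0].size == 0:
        raise ValueError("cannot project an empty mask")
    P = np.stack(
        [grid.axis_coords(ax)[idx[ax]] for ax in range(3)], axis=1
    ).astype(float)
    d, u, v = beam_basis(beam.gantry, beam.collimator)
    iso = np.asarray(beam.isocenter, dtype=float)
    source = iso - beam.sad_cm * 10.0 * d
    w = P - source
    t = w @ d
    scale = (beam.sad_cm * 10.0) / t
    up = (w @ u) * scale
    vp = (w @ v) * scale
    pad = 2.0 * pixel_mm
    us = np.arange(up.min() - pad, up.max() + pad + pixel_mm, pixel_mm)
    vs = np.arange(vp.min() - pad, vp.max() + pad + pixel_mm, pixel_mm)
    bev = np.zeros((us.size, vs.size), dtype=bool)
    iu = np.clip(np.rint((up - us[0]) / pixel_mm).astype(int), 0, us.size - 1)
    iv = np.clip(np.rint((vp - vs[0]) / pixel_mm).astype(int), 0, vs.size - 1)
    bev[iu, iv] = True
    bev = ndimage.binary_closing(bev, iterations=1)
    return us, vs, bev


def _lung_centers(structures: StructureSet) -> np.ndarray:
    lungs = structures.masks["lungs"]
    lab, n = ndimage.label(lungs)
    centers = []
    for c in ndimage.center_of_mass(lungs, lab, range(1, n + 1)):
        centers.append(
            [structures.grid.origin[ax] + c[ax] * structures.grid.spacing[ax] for ax in range(3)]
        )
    return np.asarray(centers)


def recreate_classic_appa(
    ct: ImageVolume,
    structures: StructureSet,
    rx_gy: float = 13.2,
    constants: PhysicsConstants | None = None,
    is_pediatric: bool = False,
    grid: Grid | None = None,
    mu_rate: float = 200.0,
) -> tuple[list[Beam], DoseGrid, dict]:
    """Classic whole-body opposed fields at extended distance.

    10 MV AP/PA beams, 40 x 40 cm field collimated at 45 degrees, SAD
    400 cm; a 1 cm Lucite spoiler adds water-equivalent build-up; MU is set
    from the maximum body thickness to deliver the prescription at
    mid-separation; cerrobend lung blocks (lung outline contracted 5 mm in
    the beam's eye view) are solved to leave 10 Gy (adult) or 8 Gy
    (pediatric) at mid-lung, and kidney blocks are 4 cm thick.
    """
    constants = constants or PhysicsConstants()
    grid = grid or default_dose_grid(ct)
    structures.require("body", "lungs", "kidneys")
    body = structures.masks["body"]
    sgrid = structures.grid

    # single isocenter at the body centroid
    idx = np.nonzero(body)
    iso = tuple(
        float(np.mean(sgrid.axis_coords(ax)[idx[ax]])) for ax in range(3)
    )
    # maximum AP thickness and its location
    sy = sgrid.spacing[1]
    thickness = body.sum(axis=1) * sy  # (nx, nz) mm
    ix, iz = np.unravel_index(np.argmax(thickness), thickness.shape)
    t_max = float(thickness[ix, iz])
    ys = sgrid.axis_coords(1)
    col = body[ix, :, iz]
    y_mid = float(0.5 * (ys[col].min() + ys[col].max()))
    p_mid = np.array([[sgrid.axis_coords(0)[ix], y_mid, sgrid.axis_coords(2)[iz]]])

    half = 80.0  # cm at the isocenter plane: 40 cm field at 100 cm, SAD 400
    spoiler_wed = 10.0 * constants.lucite_density
    beams = []
    for gantry, tag in ((0.0, "AP"), (180.0, "PA")):
        beams.append(
            Beam(
                isocenter=iso,
                gantry=gantry,
                collimator=45.0,
                energy=10,
                sad_cm=400.0,
                mu=100.0,
                mu_rate=mu_rate,
                segments=[BeamSegment((-half, half, -half, half), 1.0)],
                technique="classic_appa",
                spoiler_wed_mm=spoiler_wed,
                label=f"classic_{tag}",
            )
        )

    density = density_from_hu(ct.values, constants)
    # MU from the open beams: prescription at mid-separation of max thickness
    unit = sum(
        float(dose_at_points(b, p_mid, ct, constants, density=density)[0]) for b in beams
    )
    if unit <= 0:
        raise ValueError("open classic beams deliver no dose at mid-separation")
    mu_each = rx_gy / unit * 100.0
    beams = [replace(b, mu=mu_each) for b in beams]

    # open mid-lung dose -> lung block thickness (closed form inversion)
    lung_pts = _lung_centers(structures)
    d_open_midlung = float(
        np.mean(
            np.sum(
                [dose_at_points(b, lung_pts, ct, constants, density=density) for b in beams],
                axis=0,
            )
        )
    )
    target_lung = 8.0 if is_pediatric else 10.0
    mu_cer = constants.cerrobend_mu_per_cm[10]
    t_lung_cm = max(0.0, float(np.log(max(d_open_midlung, 1e-9) / target_lung)) / mu_cer) \
        if d_open_midlung > target_lung else 0.0

    blocked = []
    for b in beams:
        blocks = []
        if t_lung_cm > 0:
            us, vs, bev = _project_mask_bev(structures.masks["lungs"], sgrid, b)
            bev = ndimage.binary_erosion(bev, iterations=1)  # 5 mm contraction
            if not bev.any():
                raise ValueError("lung block shape is empty after contraction")
            blocks.append(Block(us, vs, bev, t_lung_cm, mu_cer))
        us, vs, bev = _project_mask_bev(structures.masks["kidneys"], sgrid, b)
        if not bev.any():
            raise ValueError("kidney block shape is empty")
        blocks.append(Block(us, vs, bev, 4.0, mu_cer))
        blocked.append(replace(b, blocks=blocks))

    dose = DoseGrid.zeros(grid)
    for b in blocked:
        dose = dose + compute_beam_dose(b, ct, constants, grid=grid, density=density)

    blocked_midlung = float(
        np.mean(
            np.sum(
                [dose_at_points(b, lung_pts, ct, constants, density=density) for b in blocked],
                axis=0,
            )
        )
    )
    info = {
        "isocenter_mm": iso,
        "max_thickness_mm": t_max,
        "mu_per_beam": mu_each,
        "open_midlung_gy": d_open_midlung,
        "lung_block_thickness_cm": t_lung_cm,
        "blocked_midlung_gy": blocked_midlung,
        "target_midlung_gy": target_lung,
    }
    return blocked, dose, info
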