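# tbiplan

A desk-scale toolkit for **multi-isocenter VMAT total-body irradiation
(TBI)** planning studies. Total body irradiation conditions patients for
hematopoietic stem-cell transplantation; replacing the classic opposed
whole-body fields at extended distance with multi-isocenter
volumetric-modulated arc therapy (VMAT) improves dose uniformity and organ
sparing, but makes plans sensitive to per-isocenter setup errors because
adjacent fields must match at junctions. `tbiplan` implements the full
sim-to-treat geometry of such a workflow — and makes every junction
property testable — without any commercial planning system or patient
data:

- **phantom** — synthetic whole-body CT phantoms (analytic solids with
  lungs, kidneys, pelvis fiducials) and the paired supine head-first (SHF)
  / supine feet-first (SFF) scans at 5 mm slices;
- **stitching** — rigid SFF→SHF registration in the pelvis overlap and
  whole-body volume assembly;
- **segmentation** — PTV construction (body contracted 3 mm from the skin,
  lungs and kidneys excluded) and rule-based division into VMAT and AP/PA
  sub-targets with optimization feathering zones (OFZs), isocenters, and
  junction points;
- **dose_model / planning** — feathered three-segment AP/PA beam pairs,
  nine-beam step-wedge junction fluence, idealized VMAT surrogate doses, a
  classic extended-SSD AP/PA comparator with cerrobend lung/kidney blocks,
  and DVH metrics, all on a transparent primary-beam dose engine (5 mm
  dose grid);
- **plan_io** — conversion of the whole-body plan into head-first and
  feet-first delivery plans (gantry mirror + half-turn collimator
  rotation) with voxelwise dose-equivalence verification;
- **robustness** — Monte-Carlo per-isocenter setup errors under the
  image-guided correction policy (lateral/vertical corrected, longitudinal
  locked to the planned table shifts) and junction dose-error laws.

## The rules at the core

The sub-target division is driven by machine constraints. With an MLC
travel limit of `t = 14.5` cm, split arcs double the usable field span,
a field margin `m = 0.5` cm is kept per side, and a `w = 5` cm feathering
zone is shared between neighbours:

    field length      F = 2 t           = 29 cm
    optimization cap  O = F − 2 m       = 28 cm
    sub-target cap    L = O − w         = 23 cm

The first VMAT sub-target spans head-top to neck-bottom; 23 cm blocks
follow to just below the top of the legs; equal-length AP/PA sub-targets
(25, 30, or 35 cm) cover legs and feet with ≥ 5 cm margin beyond the
soles, chosen with the fewest isocenters and then the shortest length.
Each sub-target is expanded 2.5 cm at interior ends, so adjacent
optimization volumes overlap by 5 cm; complementary linear dose ramps
across that junction make the composite equal to the prescription, and a
longitudinal error δ produces a dose error of `δ / 50 mm` of the
prescription instead of a full hot/cold spot.

## Worked example

```python
import tbiplan as tp
from tbiplan.planning import build_whole_body_plan, plan_metrics

spec = tp.PhantomSpec.default_adult(180.0, seed=1, voxel_spacing=(5, 5, 5))
volume, structures = tp.generate_phantom(spec)
params = tp.SegmentationParams()
print(params.limits)

ptv = tp.build_ptv(structures, params)
sts = tp.divide_ptv(ptv, structures.grid, structures.landmarks, params)
for s in sts.subtargets:
    print(s.index, s.kind, [round(v / 10, 1) for v in s.z_interval])

plan = build_whole_body_plan(volume, structures, sts, ptv, rx_gy=13.2, fractions=8)
m = plan_metrics(plan, structures, ptv)
print({k: round(v, 1) for k, v in m["ptv"].vx.items()})
print(round(m["lungs"].dmean_gy, 2), round(m["lung_dose_rate_cgy_min"], 1))
```

prints

```
VmatLimits(field_length=29.0, opt_limit=28.0, subtarget_limit=23.0)
1 VMAT [62.4, 86.4]
2 VMAT [39.4, 62.4]
3 VMAT [16.4, 39.4]
4 VMAT [-6.6, 16.4]
5 VMAT [-29.6, -6.6]
6 APPA [-64.6, -29.6]
7 APPA [-99.6, -64.6]
{100: 94.4, 95: 96.0, 90: 96.2, 110: 2.1}
11.07 10.1
```

— a 180 cm adult divides into seven sub-targets (five VMAT, two 35 cm
AP/PA); the composite plan covers 94.4% of the PTV with the full 13.2 Gy
prescription with a 2.1% hotspot volume, holds the mean lung dose to
11.07 Gy through the surrogate's lung-sparing goal, and delivers a mean
lung dose rate of 10.1 cGy/min at the 200 MU/min lung-isocenter MU rate.
The classic extended-SSD comparator on the same phantom
(`tbiplan.planning.recreate_classic_appa`) solves a 1.27 cm cerrobend
lung-block thickness for exactly 10 Gy at mid-lung and reaches PTV
V100 = 82.2% with a 47.2% hotspot volume — the expected direction of the
plan-quality gap between the two techniques.

The same pipeline is scriptable from the shell:

```bash
tbiplan simulate-phantom --spec spec.yaml --out case/ --offset "3,-2,5"
tbiplan stitch --shf case/shf.nii.gz --sff case/sff.nii.gz --out whole.nii.gz
tbiplan segment --structures case/structures.json --out subtargets.json
tbiplan evaluate --volume case/whole.nii.gz --structures case/structures.json \
                 --subtargets subtargets.json --classic
tbiplan convert --volume case/whole.nii.gz --structures case/structures.json \
                --subtargets subtargets.json --out-shf shf.json --out-sff sff.json
tbiplan robustness --volume case/whole.nii.gz --structures case/structures.json \
                   --subtargets subtargets.json --n 500 --seed 7 --report rob.json
```

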