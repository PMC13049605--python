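"""File formats: volumetric grids (NIfTI / MetaImage), label masks,
displacement fields, plan YAML/JSON and tidy result tables.

Grids round-trip losslessly (values bit-exact for float32, geometry to
1e-6 mm).  Array axis order is (x, y, z) in memory; MetaImage IO transposes
to/from the (z, y, x) convention of SimpleITK.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .dose_engine import Beam, Plan, Spot
from .grid import DoseGrid

__all__ = [
    "save_grid",
    "load_grid",
    "save_masks",
    "load_masks",
    "save_dvf",
    "load_dvf",
    "plan_to_dict",
    "plan_from_dict",
    "save_plan",
    "load_plan",
]


def _is_nifti(path: Path) -> bool:
    s = "".join(path.suffixes)
    return s.endswith(".nii") or s.endswith(".nii.gz")


def save_grid(grid: DoseGrid, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = grid.spacing
        affine[:3, 3] = grid.origin
        nib.save(nib.Nifti1Image(np.asarray(grid.values), affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
        img.SetSpacing(tuple(float(s) for s in grid.spacing))
        img.SetOrigin(tuple(float(o) for o in grid.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported grid format: {path.name}")


def load_grid(path) -> DoseGrid:
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        affine = img.affine
        values = np.asanyarray(img.dataobj)
        spacing = tuple(float(affine[i, i]) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return DoseGrid(values, spacing, origin)
    if path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).T
        return DoseGrid(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise ValueError(f"unsupported grid format: {path.name}")


def save_masks(masks: dict[str, np.ndarray], spacing, origin, path) -> None:
    """Store named binary masks as one labelled integer volume plus a JSON
    sidecar mapping label -> name.  Masks are assumed pairwise disjoint apart
    from derived envelopes (later names overwrite earlier labels)."""
    path = Path(path)
    names = list(masks)
    label = np.zeros(next(iter(masks.values())).shape, dtype=np.int16)
    for i, name in enumerate(names, start=1):
        label[np.asarray(masks[name], bool)] = i
    save_grid(DoseGrid(label, spacing, origin), path)
    sidecar = path.with_suffix("").with_suffix("") if _is_nifti(path) else path.with_suffix("")
    with open(str(sidecar) + ".labels.json", "w") as f:
        json.dump({str(i): n for i, n in enumerate(names, start=1)}, f, indent=1)


def load_masks(path) -> tuple[dict[str, np.ndarray], tuple, tuple]:
    path = Path(path)
    grid = load_grid(path)
    sidecar = path.with_suffix("").with_suffix("") if _is_nifti(path) else path.with_suffix("")
    with open(str(sidecar) + ".labels.json") as f:
        labels = json.load(f)
    masks = {
        name: np.asarray(grid.values) == int(lbl) for lbl, name in labels.items()
    }
    return masks, grid.spacing, grid.origin


def save_dvf(dvf: np.ndarray, spacing, origin, path) -> None:
    """3-component displacement field (mm) as a 4D NIfTI volume."""
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError("displacement fields are stored as NIfTI")
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(dvf), affine), str(path))


def load_dvf(path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    affine = img.affine
    return (
        np.asanyarray(img.dataobj),
        tuple(float(affine[i, i]) for i in range(3)),
        tuple(float(affine[i, 3]) for i in range(3)),
    )


# ---------------------------------------------------------------------------
# plans


def plan_to_dict(plan: Plan) -> dict:
    return {
        "prescription_dose": plan.prescription_dose,
        "n_fractions": plan.n_fractions,
        "rbe_factor": plan.rbe_factor,
        "isocenter": list(plan.isocenter),
        "beams": [
            {
                "gantry_angle": b.gantry_angle,
                "repaint_factor": b.repaint_factor,
                "energy_layers": [
                    {
                        "nominal_range": rng_mm,
                        "spots": [
                            {
                                "lateral_position": list(s.lateral_position),
                                "nominal_range": s.nominal_range,
                                "weight": s.weight,
                                "sigma_lateral": s.sigma_lateral,
                            }
                            for s in layer
                        ],
                    }
                    for rng_mm, layer in b.energy_layers
                ],
            }
            for b in plan.beams
        ],
    }


def plan_from_dict(d: dict) -> Plan:
    beams = []
    for bd in d["beams"]:
        layers = []
        for ld in bd["energy_layers"]:
            spots = [
                Spot(
                    lateral_position=tuple(sd["lateral_position"]),
                    nominal_range=sd["nominal_range"],
                    weight=sd["weight"],
                    sigma_lateral=sd["sigma_lateral"],
                )
                for sd in ld["spots"]
            ]
            layers.append((ld["nominal_range"], spots))
        beams.append(
            Beam(
                gantry_angle=bd["gantry_angle"],
                energy_layers=layers,
                repaint_factor=bd["repaint_factor"],
            )
        )
    return Plan(
        beams=beams,
        prescription_dose=d["prescription_dose"],
        n_fractions=d["n_fractions"],
        rbe_factor=d["rbe_factor"],
        isocenter=tuple(d["isocenter"]),
    )


def save_plan(plan: Plan, path) -> None:
    path = Path(path)
    d = plan_to_dict(plan)
    with open(path, "w") as f:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(d, f, sort_keys=False)
        elif path.suffix == ".json":
            json.dump(d, f)
        else:
            raise ValueError("plans are stored as YAML or JSON")


def load_plan(path) -> Plan:
    path = Path(path)
    with open(path) as f:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(f)
        elif path.suffix == ".json":
            d = json.load(f)
        else:
            raise ValueError("plans are stored as YAML or JSON")
    return plan_from_dict(d)
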