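"""Reading and writing the package's on-disk formats.

Activity images and sinograms travel as NIfTI-1 with a JSON sidecar holding
whatever the NIfTI header cannot (units convention, timestamp, sinogram
duration/sensitivity/seed).  Phantom specs are YAML.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grid import ActivityImage, VoxelGrid
from .isotopes import IsotopeModel, get_isotope
from .phantom import GEOMETRY_TYPES, CompartmentSpec, LesionSpec, PhantomSpec

__all__ = [
    "save_image",
    "load_image",
    "save_phantom_spec",
    "load_phantom_spec",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_image(image: ActivityImage, path, extra_meta: dict | None = None) -> Path:
    """Write an :class:`ActivityImage` as NIfTI-1 plus a JSON sidecar."""
    path = Path(path)
    affine = np.diag(list(image.grid.spacing) + [1.0])
    affine[:3, 3] = image.grid.origin
    nii = nib.Nifti1Image(image.values.astype(np.float32), affine)
    nii.header.set_zooms(image.grid.spacing)
    nib.save(nii, path)
    meta = {"units": "kBq/mL", "timestamp_min": image.timestamp}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_image(path) -> ActivityImage:
    """Read a NIfTI activity image (sidecar optional)."""
    path = Path(path)
    nii = nib.load(path)
    affine = nii.affine
    spacing = tuple(float(s) for s in nii.header.get_zooms()[:3])
    origin = tuple(float(v) for v in affine[:3, 3])
    values = np.asarray(nii.get_fdata(), dtype=float)
    grid = VoxelGrid(shape=values.shape, spacing=spacing, origin=origin)
    timestamp = 0.0
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        timestamp = float(meta.get("timestamp_min", 0.0))
    return ActivityImage(grid=grid, values=values, timestamp=timestamp)


# ---------------------------------------------------------------------------
# Phantom spec YAML
# ---------------------------------------------------------------------------


def _isotope_to_dict(iso: IsotopeModel):
    return {"name": iso.name, "half_life_min": None if math.isinf(iso.half_life) else iso.half_life}


def _isotope_from_obj(obj) -> IsotopeModel:
    if isinstance(obj, str):
        return get_isotope(obj)
    half = obj.get("half_life_min")
    return IsotopeModel(obj["name"], math.inf if half is None else float(half))


def _geometry_to_dict(geom) -> dict:
    for type_name, cls in GEOMETRY_TYPES.items():
        if isinstance(geom, cls):
            d = {"type": type_name}
            for key, val in geom.__dict__.items():
                d[key] = _to_plain(val)
            return d
    raise TypeError(f"unknown geometry {type(geom).__name__}")


def _to_plain(val):
    if isinstance(val, tuple):
        return [_to_plain(v) for v in val]
    if isinstance(val, (np.floating, np.integer)):
        return val.item()
    return val


def _geometry_from_dict(d: dict):
    d = dict(d)
    type_name = d.pop("type")
    try:
        cls = GEOMETRY_TYPES[type_name]
    except KeyError:
        raise ValueError(
            f"unknown geometry type {type_name!r}; expected one of {sorted(GEOMETRY_TYPES)}"
        ) from None
    kwargs = {}
    for key, val in d.items():
        if isinstance(val, list):
            val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        kwargs[key] = val
    return cls(**kwargs)


def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "grid": {
            "shape": list(spec.grid.shape),
            "spacing": list(spec.grid.spacing),
            "origin": list(spec.grid.origin),
        },
        "reference_time": spec.reference_time,
        "texture_sigma": spec.texture_sigma,
        "compartments": [
            {
                "name": c.name,
                "geometry": _geometry_to_dict(c.geometry),
                "concentration": c.concentration,
                "isotope": _isotope_to_dict(c.isotope),
            }
            for c in spec.compartments
        ],
        "lesions": [
            {
                "id": les.id,
                "center": list(les.center),
                "diameter": les.diameter,
                "concentration": les.concentration,
                "isotope": _isotope_to_dict(les.isotope),
            }
            for les in spec.lesions
        ],
    }


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    try:
        grid = VoxelGrid(
            shape=tuple(d["grid"]["shape"]),
            spacing=tuple(d["grid"].get("spacing", (3.65, 3.65, 3.27))),
            origin=tuple(d["grid"].get("origin", (0.0, 0.0, 0.0))),
        )
        compartments = [
            CompartmentSpec(
                name=c["name"],
                geometry=_geometry_from_dict(c["geometry"]),
                concentration=float(c["concentration"]),
                isotope=_isotope_from_obj(c.get("isotope", "F-18")),
            )
            for c in d["compartments"]
        ]
        lesions = [
            LesionSpec(
                id=les["id"],
                center=tuple(les["center"]),
                diameter=float(les["diameter"]),
                concentration=float(les["concentration"]),
                isotope=_isotope_from_obj(les.get("isotope", "Na-22")),
            )
            for les in d.get("lesions", [])
        ]
    except KeyError as exc:
        raise ValueError(f"phantom spec missing required key: {exc}") from exc
    return PhantomSpec(
        grid=grid,
        compartments=compartments,
        lesions=lesions,
        reference_time=float(d.get("reference_time", 0.0)),
        texture_sigma=float(d.get("texture_sigma", 0.0)),
    )


def save_phantom_spec(spec: PhantomSpec, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(phantom_spec_to_dict(spec), sort_keys=False))
    return path


def load_phantom_spec(path) -> PhantomSpec:
    with open(path) as fh:
        return phantom_spec_from_dict(yaml.safe_load(fh))
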