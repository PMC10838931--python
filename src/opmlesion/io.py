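"""Readers and writers for surfaces, lesion labels, channel tables and
cohorts.

Surfaces go to GIfTI (``.surf.gii``, via nibabel) or Wavefront OBJ (via
trimesh); lesion patches to a per-vertex label CSV with columns
``patient_id, lesion_id, vertex_index``; sensor channel tables to a
BIDS-MEG-like TSV.  A cohort directory bundles the two surfaces, the
lesion CSV and a JSON manifest.
"""

from __future__ import annotations

import json
import pathlib

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .cohort import Cohort, CohortConfig, Patient, SyntheticHead
from .geometry import TriangleMesh, VertexPatch
from .sensors import SensorArray

__all__ = [
    "save_mesh",
    "load_mesh",
    "save_lesions_csv",
    "load_lesions_csv",
    "save_channel_table",
    "load_channel_table",
    "save_cohort",
    "load_cohort",
]


def save_mesh(mesh: TriangleMesh, path) -> None:
    """Write a surface as GIfTI (.gii) or OBJ, chosen by extension."""
    path = pathlib.Path(path)
    if path.suffix == ".gii":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif path.suffix == ".obj":
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        path.write_text(trimesh.exchange.obj.export_obj(tm, include_normals=False))
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")


def load_mesh(path) -> TriangleMesh:
    path = pathlib.Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        vertices = img.darrays[0].data.astype(np.float64)
        faces = img.darrays[1].data.astype(np.int64)
        return TriangleMesh(vertices, faces)
    if path.suffix == ".obj":
        tm = trimesh.load(str(path), file_type="obj", process=False)
        return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    raise ValueError(f"unsupported mesh format {path.suffix!r}")


def save_lesions_csv(patients, path) -> None:
    rows = []
    for p in patients:
        for les in p.lesions:
            for v in les.indices:
                rows.append((p.id, les.label, int(v)))
    pd.DataFrame(rows, columns=["patient_id", "lesion_id", "vertex_index"]).to_csv(
        path, index=False
    )


def load_lesions_csv(path, mesh: TriangleMesh):
    df = pd.read_csv(path)
    patients = []
    for pid, pgrp in df.groupby("patient_id", sort=True):
        lesions = []
        for lid, lgrp in pgrp.groupby("lesion_id", sort=True):
            lesions.append(
                VertexPatch(mesh, lgrp["vertex_index"].to_numpy(), label=str(lid))
            )
        patients.append(Patient(id=str(pid), lesions=tuple(lesions)))
    return patients


def save_channel_table(array: SensorArray, path) -> None:
    array.channel_table().to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_channel_table(path) -> SensorArray:
    """Rebuild a SensorArray from its channel TSV.

    The stored radial/tangential channel orientations define the triad
    (second tangential axis by right-hand rule); channel positions and
    orientations round-trip exactly up to float formatting.
    """
    df = pd.read_csv(path, sep="\t")
    rad = df[df["axis"] == "radial"]
    tan = df[df["axis"] == "tangential"]
    positions = rad[["x", "y", "z"]].to_numpy()
    r = rad[["ox", "oy", "oz"]].to_numpy()
    t1 = tan[["ox", "oy", "oz"]].to_numpy()
    t2 = np.cross(r, t1)
    triads = np.stack([r, t1, t2], axis=1)
    return SensorArray(
        positions=positions,
        triads=triads,
        tangent_angles=np.zeros(len(positions)),
    )


def save_cohort(cohort: Cohort, directory) -> None:
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_mesh(cohort.head.cortex, directory / "cortex.obj")
    save_mesh(cohort.head.scalp, directory / "scalp.obj")
    save_lesions_csv(cohort.patients, directory / "lesions.csv")
    cohort.save_manifest(directory / "manifest.json")


def load_cohort(directory) -> Cohort:
    directory = pathlib.Path(directory)
    cortex = load_mesh(directory / "cortex.obj")
    scalp = load_mesh(directory / "scalp.obj")
    head = SyntheticHead(cortex=cortex, scalp=scalp)
    patients = load_lesions_csv(directory / "lesions.csv", cortex)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg = manifest.get("config", {})
    config = CohortConfig(
        area_range=tuple(cfg.get("area_range", (200.0, 1000.0))),
        separation=tuple(cfg.get("separation", (30.0, None))),
        k_range=tuple(cfg.get("k_range", (2, 14))),
        count_p=cfg.get("count_p", 0.6),
    )
    return Cohort(
        head=head,
        patients=tuple(patients),
        config=config,
        seed=manifest.get("seed", -1),
    )
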