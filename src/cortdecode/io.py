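"""Readers and writers for the standard on-disk formats.

Volumes are NIfTI-1 (TR carried in the time-axis zoom), meshes GIfTI (with
an OFF ASCII fallback), label schedules BIDS-style events TSV, nuisance
regressors plain TSV, and feature matrices TSV with a JSON sidecar that
records the extraction parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import LabelSchedule
from .mesh import CorticalMesh
from .preproc import NuisanceSet
from .surface import FeatureMatrix
from .volume import VolumeTimeSeries

__all__ = [
    "save_volume",
    "load_volume",
    "save_mesh",
    "load_mesh",
    "save_events",
    "load_events",
    "save_nuisance",
    "load_nuisance",
    "save_feature_matrix",
    "load_feature_matrix",
]


def save_volume(vol: VolumeTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    zooms = img.header.get_zooms()[:3] + (vol.tr_s,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, session: int = 1, run: int = 1) -> VolumeTimeSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    tr = float(img.header.get_zooms()[3])
    return VolumeTimeSeries(data=data, affine=img.affine, tr_s=tr, session=session, run=run)


def save_mesh(mesh: CorticalMesh, path: str | Path) -> Path:
    """Write GIfTI (``.gii``) or OFF ASCII (``.off``) by extension."""
    path = Path(path)
    if path.suffix == ".off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        return path
    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))
    return path


def load_mesh(path: str | Path) -> CorticalMesh:
    path = Path(path)
    if path.suffix == ".off":
        with open(path) as fh:
            tokens = fh.read().split()
        if tokens[0] != "OFF":
            raise ValueError(f"{path} is not an OFF file")
        nv, nf = int(tokens[1]), int(tokens[2])
        vals = np.asarray(tokens[4: 4 + 3 * nv], dtype=np.float64).reshape(nv, 3)
        rest = tokens[4 + 3 * nv:]
        faces = np.empty((nf, 3), dtype=np.int64)
        i = 0
        for fi in range(nf):
            k = int(rest[i])
            if k != 3:
                raise ValueError("only triangular OFF faces are supported")
            faces[fi] = [int(rest[i + 1]), int(rest[i + 2]), int(rest[i + 3])]
            i += k + 1
        return CorticalMesh(vertices=vals, faces=faces)
    img = nib.load(str(path))
    verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return CorticalMesh(vertices=np.asarray(verts, float), faces=np.asarray(faces, int))


def save_events(schedule: LabelSchedule, path: str | Path) -> Path:
    path = Path(path)
    cols = ["onset", "duration", "stress_level", "run", "session"]
    schedule.table[cols].to_csv(path, sep="\t", index=False)
    return path


def load_events(path: str | Path, tr_s: float = 1.5, frames_per_report: int = 10) -> LabelSchedule:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values(["session", "run", "onset"]).reset_index(drop=True)
    interval = frames_per_report * tr_s
    df["report_index"] = (df["onset"] / interval).round().astype(int)
    df["group"] = np.arange(len(df))
    return LabelSchedule(table=df, frames_per_report=frames_per_report, tr_s=tr_s)


def save_nuisance(nuis: NuisanceSet, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(nuis.regressors, columns=list(nuis.names)).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_nuisance(path: str | Path) -> NuisanceSet:
    df = pd.read_csv(path, sep="\t")
    return NuisanceSet(regressors=df.to_numpy(dtype=np.float64), names=tuple(df.columns))


def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> tuple[Path, Path]:
    """One row per sample: session, run, group, label, f0001...fK, plus a
    JSON sidecar with feature ids and extraction parameters."""
    path = Path(path)
    width = max(4, len(str(fm.n_features)))
    cols = {f"f{i + 1:0{width}d}": fm.data[:, i] for i in range(fm.n_features)}
    head = {}
    if fm.session is not None:
        head["session"] = fm.session
    if fm.run is not None:
        head["run"] = fm.run
    if fm.groups is not None:
        head["group"] = fm.groups
    if fm.labels is not None:
        head["label"] = fm.labels
    pd.DataFrame({**head, **cols}).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    meta = {k: v for k, v in fm.meta.items()}
    meta["feature_ids"] = np.asarray(fm.feature_ids).tolist()
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    return path, sidecar


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    feature_ids = np.asarray(meta.pop("feature_ids", np.arange(len(feat_cols))))
    get = lambda c: df[c].to_numpy() if c in df.columns else None
    return FeatureMatrix(
        data=df[feat_cols].to_numpy(dtype=np.float64),
        feature_ids=feature_ids,
        labels=get("label"),
        groups=get("group"),
        session=get("session"),
        run=get("run"),
        meta=meta,
    )
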