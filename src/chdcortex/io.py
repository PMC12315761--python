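"""Reading and writing the on-disk dataset bundle.

A dataset directory holds ``cohort.csv`` (one row per subject), the three
vertex-wise metric matrices, and ``manifest.json`` recording vertex count,
0-based midline-mask indices, hemisphere grid shape, and subject order.
Metric matrices are stored either consolidated (``ct.tsv`` etc., vertices x
subjects with a subject-id header) or as per-subject plain-text vertex
files (one float per line), the convention surface pipelines emit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import grid_geometry
from .simulate import METRICS, VertexFeatureSet


class DatasetFormatError(ValueError):
    """A file in the bundle is inconsistent with the manifest."""


def write_dataset(cohort: pd.DataFrame, features: VertexFeatureSet, path,
                  fmt: str = "tsv", seed=None, spec=None) -> Path:
    """Write a cohort + feature bundle under ``path``.

    ``fmt="tsv"`` writes one vertices-x-subjects table per metric;
    ``fmt="civet"`` writes one ``<metric>/<subject>.txt`` vertex file per
    subject per metric.  Missing clinical values serialize as empty fields,
    never as zeros.
    """
    if list(cohort["subject_id"]) != list(features.subject_order):
        raise ValueError("cohort subject order differs from feature subject order")
    if fmt not in ("tsv", "civet"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path / "cohort.csv", index=False)

    geom = features.geometry
    for m, X in features.metrics.items():
        if fmt == "tsv":
            pd.DataFrame(X, columns=features.subject_order).to_csv(
                path / f"{m}.tsv", sep="\t", index=False
            )
        else:
            mdir = path / m
            mdir.mkdir(exist_ok=True)
            for j, sid in enumerate(features.subject_order):
                np.savetxt(mdir / f"{sid}.txt", X[:, j], fmt="%.10g")

    manifest = {
        "format": fmt,
        "n_vertices": int(geom.n_vertices),
        "n_subjects": int(features.n_subjects),
        "grid_shape": list(geom.grid_shape) if geom.grid_shape else None,
        "mask_indices": np.flatnonzero(geom.midline_mask).tolist(),
        "subject_order": list(features.subject_order),
        "metrics": list(METRICS),
        "seed": seed,
        "spec": spec.to_dict() if hasattr(spec, "to_dict") else spec,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def _read_metric(path: Path, m: str, manifest: dict) -> np.ndarray:
    n_vert = manifest["n_vertices"]
    subjects = manifest["subject_order"]
    if manifest["format"] == "tsv":
        f = path / f"{m}.tsv"
        if not f.exists():
            raise DatasetFormatError(f"missing metric file {f}")
        df = pd.read_csv(f, sep="\t")
        if list(df.columns) != list(subjects):
            raise DatasetFormatError(f"{f}: subject columns disagree with manifest")
        if len(df) != n_vert:
            raise DatasetFormatError(
                f"{f}: expected {n_vert} vertex rows, found {len(df)}"
            )
        return df.to_numpy(float)
    X = np.empty((n_vert, len(subjects)))
    for j, sid in enumerate(subjects):
        f = path / m / f"{sid}.txt"
        if not f.exists():
            raise DatasetFormatError(f"missing vertex file {f}")
        v = np.loadtxt(f, ndmin=1)
        if v.size != n_vert:
            raise DatasetFormatError(
                f"{f}: expected {n_vert} values, found {v.size}"
            )
        X[:, j] = v
    return X


def read_dataset(path, validate: bool = True):
    """Read a bundle written by :func:`write_dataset`.

    Returns ``(cohort, features)``; invariants are re-checked on load.
    """
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise DatasetFormatError(f"no manifest.json under {path}")
    manifest = json.loads(mf.read_text())

    cohort = pd.read_csv(path / "cohort.csv")
    if list(cohort["subject_id"]) != list(manifest["subject_order"]):
        raise DatasetFormatError(
            "cohort.csv subject order disagrees with manifest subject_order"
        )

    if manifest.get("grid_shape"):
        geom = grid_geometry(*manifest["grid_shape"])
    else:
        raise DatasetFormatError("manifest lacks grid_shape; cannot rebuild geometry")
    if geom.n_vertices != manifest["n_vertices"]:
        raise DatasetFormatError(
            f"manifest n_vertices {manifest['n_vertices']} inconsistent "
            f"with grid_shape {manifest['grid_shape']}"
        )
    stored_mask = np.zeros(geom.n_vertices, dtype=bool)
    stored_mask[manifest["mask_indices"]] = True
    if not np.array_equal(stored_mask, geom.midline_mask):
        raise DatasetFormatError("manifest mask indices disagree with geometry")

    mats = {m: _read_metric(path, m, manifest) for m in METRICS}
    features = VertexFeatureSet(
        ct=mats["ct"], sa=mats["sa"], gi=mats["gi"],
        geometry=geom, subject_order=list(manifest["subject_order"]),
    )
    if validate:
        features.validate()
    return cohort, features
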