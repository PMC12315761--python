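"""Building the non-negative factorization input from harmonized features.

Three steps: midline masking, vertex-wise residualization of each metric on
total cortical grey-matter volume (so factorization variance is independent
of global brain size), and assembly of the vertices x (subjects * metrics)
matrix — per-vertex z-scoring within each metric block (the metrics live on
different scales) followed by a single global minimum shift to enforce
non-negativity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .simulate import METRICS, VertexFeatureSet


@dataclass
class OpnmfInput:
    """Prepared non-negative input matrix V with column provenance."""

    V: np.ndarray  # vertices x (subjects * metrics), min exactly 0
    column_labels: list  # (subject_id, metric) per column
    shift_value: float  # the subtracted global minimum z-score
    mask: np.ndarray  # vertex mask that was applied (True = removed)

    def __post_init__(self):
        if self.V.shape[1] != len(self.column_labels):
            raise ValueError("every column of V must carry a (subject, metric) label")

    def columns_for_metric(self, metric: str) -> np.ndarray:
        return np.array([j for j, (_, m) in enumerate(self.column_labels) if m == metric])

    def save(self, matrix_path, sidecar_path):
        np.savetxt(matrix_path, self.V, fmt="%.8g", delimiter="\t")
        meta = {
            "shift_value": self.shift_value,
            "column_labels": [list(c) for c in self.column_labels],
            "mask_indices": np.flatnonzero(self.mask).tolist(),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh)


def apply_midline_mask(features: VertexFeatureSet, mask=None) -> VertexFeatureSet:
    """Drop masked vertex rows from all three metric matrices.

    ``mask`` defaults to the geometry's midline mask; boolean (True =
    remove) or integer indices are accepted.  On the conventional
    full-resolution surface this takes 81,924 vertices to 77,122.
    """
    geom = features.geometry
    if mask is None:
        mask = geom.midline_mask
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.size != geom.n_vertices:
            raise ValueError(
                f"boolean mask length {mask.size} != vertex count {geom.n_vertices}"
            )
        drop = mask
    else:
        if mask.size and (mask.min() < 0 or mask.max() >= geom.n_vertices):
            raise ValueError("mask indices out of range")
        drop = np.zeros(geom.n_vertices, dtype=bool)
        drop[mask] = True
    keep = ~drop
    if not keep.any():
        raise ValueError("mask removes every vertex")
    masked = VertexFeatureSet(
        ct=features.ct[keep], sa=features.sa[keep], gi=features.gi[keep],
        geometry=geom, subject_order=list(features.subject_order),
    )
    masked.kept_indices = np.flatnonzero(keep)
    return masked


def residualize_on_volume(matrices: dict, volume) -> dict:
    """OLS-residualize each vertex row of each metric on total volume.

    Per (vertex, metric) row, fits ``feature ~ 1 + volume`` across subjects
    and returns the mean-zero residuals.  ``matrices`` maps metric name to
    a vertices x subjects array.
    """
    if hasattr(matrices, "metrics"):  # accept a VertexFeatureSet directly
        matrices = matrices.metrics
    v = np.asarray(volume, float)
    if not np.isfinite(v).all() or (v <= 0).any():
        raise ValueError("volume must be finite and positive for all subjects")
    if v.size < 3:
        raise ValueError("need at least 3 subjects to residualize")
    vc = v - v.mean()
    denom = vc @ vc
    if denom == 0:
        raise ValueError("constant volume vector: residualization is degenerate")
    out = {}
    for m, X in matrices.items():
        X = np.asarray(X, float)
        if X.shape[1] != v.size:
            raise ValueError(f"{m}: {X.shape[1]} columns vs {v.size} volumes")
        slope = (X @ vc) / denom
        out[m] = X - X.mean(axis=1, keepdims=True) - np.outer(slope, vc)
    return out


def build_opnmf_input(matrices: dict, subject_order,
                      metric_order=METRICS, mask=None) -> OpnmfInput:
    """Assemble the z-scored, minimum-shifted non-negative input matrix.

    Each metric block is horizontally concatenated (metric-major column
    order); every vertex row is z-scored within its metric block across
    subjects; the single matrix-wide minimum is then subtracted so
    ``min(V) == 0`` exactly.  Zero-variance rows within a metric are set to
    zero rather than divided by zero.
    """
    blocks, labels = [], []
    for m in metric_order:
        X = np.asarray(matrices[m], float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = np.where(sd > 0, (X - mu) / sd, 0.0)
        blocks.append(Z)
        labels.extend((sid, m) for sid in subject_order)
    Z = np.hstack(blocks)
    shift = float(Z.min())
    V = Z - shift
    # guard against float fuzz: the minimum must be exactly zero
    V[np.unravel_index(np.argmin(V), V.shape)] = 0.0
    return OpnmfInput(
        V=V, column_labels=labels, shift_value=shift,
        mask=np.zeros(0, dtype=bool) if mask is None else np.asarray(mask),
    )
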