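"""Surface geometry stand-in for vertex-wise cortical analyses.

Real cortical surfaces are triangulated meshes; every property the pipeline
relies on (a fixed vertex count, hemisphere labels, a neighbourhood relation
for spatial contiguity, and a midline exclusion mask) is captured here by a
two-hemisphere rectangular grid with 4-neighbour adjacency.  The conventional
full-resolution surface has 81,924 vertices of which 77,122 survive midline
masking; synthetic geometries default to a much smaller grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


@dataclass
class Geometry:
    """Vertex topology: hemisphere labels, adjacency and midline mask.

    Attributes
    ----------
    n_vertices : int
        Total vertex count across both hemispheres.
    hemisphere : np.ndarray
        Per-vertex label, ``"L"`` or ``"R"``.
    adjacency : sparse.csr_matrix
        Symmetric, irreflexive boolean vertex-neighbour relation.
    midline_mask : np.ndarray
        Boolean, True = vertex excluded from analysis.
    grid_shape : tuple
        (rows, cols) of the per-hemisphere grid, kept so geometry can be
        reconstructed from a manifest.
    """

    n_vertices: int
    hemisphere: np.ndarray
    adjacency: sparse.csr_matrix
    midline_mask: np.ndarray
    grid_shape: tuple = field(default=None)

    def __post_init__(self):
        if self.n_vertices <= 0:
            raise ValueError("n_vertices must be positive")
        a = self.adjacency
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        if int(self.midline_mask.sum()) >= self.n_vertices:
            raise ValueError("midline mask may not cover every vertex")

    @property
    def unmasked(self) -> np.ndarray:
        """Indices of vertices retained after midline masking."""
        return np.flatnonzero(~self.midline_mask)

    @property
    def n_unmasked(self) -> int:
        return int((~self.midline_mask).sum())

    def neighbors(self, v: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[v] : self.adjacency.indptr[v + 1]
        ]


def grid_geometry(n_rows: int = 25, n_cols: int = 40) -> Geometry:
    """Build a two-hemisphere grid geometry.

    Each hemisphere is an ``n_rows x n_cols`` lattice with 4-neighbour
    adjacency; hemispheres are not connected to each other.  The first grid
    column of each hemisphere (the column facing the interhemispheric
    fissure) is flagged as midline and masked, mimicking the exclusion of
    unreliable midline vertices on real surfaces.
    """
    per_hemi = n_rows * n_cols
    n = 2 * per_hemi
    hemi = np.array(["L"] * per_hemi + ["R"] * per_hemi)

    rows_idx, cols_idx = [], []
    for h in range(2):
        off = h * per_hemi
        idx = np.arange(per_hemi).reshape(n_rows, n_cols) + off
        # horizontal and vertical lattice edges, both directions
        for a, b in ((idx[:, :-1], idx[:, 1:]), (idx[:-1, :], idx[1:, :])):
            rows_idx.extend([a.ravel(), b.ravel()])
            cols_idx.extend([b.ravel(), a.ravel()])
    rows_idx = np.concatenate(rows_idx)
    cols_idx = np.concatenate(cols_idx)
    adj = sparse.csr_matrix(
        (np.ones(rows_idx.size, dtype=bool), (rows_idx, cols_idx)), shape=(n, n)
    )

    mask = np.zeros(n, dtype=bool)
    for h in range(2):
        off = h * per_hemi
        idx = np.arange(per_hemi).reshape(n_rows, n_cols) + off
        mask[idx[:, 0]] = True

    return Geometry(
        n_vertices=n,
        hemisphere=hemi,
        adjacency=adj,
        midline_mask=mask,
        grid_shape=(n_rows, n_cols),
    )
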