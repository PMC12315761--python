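"""Split-half stability analysis for choosing the number of components.

For each candidate rank k, the subjects are repeatedly split into random
halves, each half is re-prepared independently (volume residualization and
z-scoring within the half, so no information leaks across halves) and
factorized, and the two half-sample component sets are compared after
optimal one-to-one Hungarian matching on cosine similarity.  A rank is a
good choice when its components reproduce across halves (high mean cosine)
while the full-sample reconstruction error has stopped improving
appreciably — high spatial stability and low reconstruction error with
minimal complexity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .opnmf import fit_opnmf, match_components, reconstruction_error
from .prep import build_opnmf_input, residualize_on_volume


@dataclass
class StabilityCurve:
    k_grid: list
    mean_similarity: np.ndarray
    sd_similarity: np.ndarray
    recon_error: np.ndarray       # full-data error per k
    error_gradient: np.ndarray    # forward difference: gain from k -> next k
    n_splits: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_grid,
            "mean_similarity": self.mean_similarity,
            "sd_similarity": self.sd_similarity,
            "recon_error": self.recon_error,
            "error_gradient": self.error_gradient,
        })


def _prepare(matrices: dict, volume, subject_idx, subject_order,
             residualize: bool):
    sub = {m: X[:, subject_idx] for m, X in matrices.items()}
    order = [subject_order[i] for i in subject_idx]
    if residualize:
        sub = residualize_on_volume(sub, np.asarray(volume)[subject_idx])
    return build_opnmf_input(sub, order)


def split_half_stability(matrices: dict, volume, subject_order, k_grid,
                         n_splits: int = 10, seed: int = 0,
                         residualize: bool = True,
                         max_iter: int = 100_000, tol: float = 1e-5,
                         check_every: int = 10) -> StabilityCurve:
    """Compute the stability/accuracy curve over candidate ranks.

    ``matrices`` holds the (masked, harmonized) vertices x subjects metric
    matrices.  Deterministic given ``seed``: the same split sequence and the
    deterministic NNDSVD-initialized fits reproduce the curve bitwise.
    """
    n = len(subject_order)
    if n < 4:
        raise ValueError("split-half stability needs at least 4 subjects")
    k_grid = list(k_grid)
    half = n // 2
    n_metrics = len(matrices)
    if max(k_grid) > half * n_metrics:
        raise ValueError(
            f"k={max(k_grid)} infeasible for half-sample column count "
            f"{half * n_metrics}"
        )
    rng = np.random.default_rng(seed)

    full = _prepare(matrices, volume, np.arange(n), subject_order, residualize)
    recon = np.empty(len(k_grid))
    for i, k in enumerate(k_grid):
        res = fit_opnmf(full.V, k, max_iter=max_iter, tol=tol,
                        check_every=check_every)
        recon[i] = reconstruction_error(full.V, res.W)

    sims = np.empty((len(k_grid), n_splits))
    for s in range(n_splits):
        perm = rng.permutation(n)
        idx_a, idx_b = np.sort(perm[:half]), np.sort(perm[half:])
        prep_a = _prepare(matrices, volume, idx_a, subject_order, residualize)
        prep_b = _prepare(matrices, volume, idx_b, subject_order, residualize)
        for i, k in enumerate(k_grid):
            fa = fit_opnmf(prep_a.V, k, max_iter=max_iter, tol=tol,
                           check_every=check_every)
            fb = fit_opnmf(prep_b.V, k, max_iter=max_iter, tol=tol,
                           check_every=check_every)
            _, cosines = match_components(fa.W, fb.W)
            sims[i, s] = cosines.mean()

    gradient = np.full(len(k_grid), np.nan)
    if len(k_grid) > 1:
        gradient[:-1] = np.diff(recon)
    return StabilityCurve(
        k_grid=k_grid,
        mean_similarity=sims.mean(axis=1),
        sd_similarity=sims.std(axis=1, ddof=1) if n_splits > 1
        else np.zeros(len(k_grid)),
        recon_error=recon,
        error_gradient=gradient,
        n_splits=n_splits,
        seed=seed,
    )


def select_k(curve: StabilityCurve, stability_floor: float = 0.8,
             error_gain_floor: float = 0.01):
    """Pick the smallest rank that is stable and past the error elbow.

    A rank qualifies when its mean split-half similarity is at least
    ``stability_floor`` and the absolute further error gain (forward
    gradient) is below ``error_gain_floor`` of the initial reconstruction
    error.  If no rank qualifies, the smallest grid value is returned with
    a ``no_elbow`` flag.

    Returns ``(selected_k, report)``.
    """
    if not len(curve.k_grid):
        raise ValueError("empty k grid")
    initial = curve.recon_error[0]
    candidates = []
    for i, k in enumerate(curve.k_grid):
        grad = curve.error_gradient[i]
        # the elbow test asks whether *adding* components still buys accuracy:
        # the gain is the error decrease to the next rank (fits at higher rank
        # can land in worse local optima, which is certainly not a gain)
        gain = 0.0 if np.isnan(grad) else max(0.0, -grad)
        flat = gain < error_gain_floor * initial
        stable = curve.mean_similarity[i] >= stability_floor
        candidates.append({
            "k": int(k),
            "mean_similarity": float(curve.mean_similarity[i]),
            "recon_error": float(curve.recon_error[i]),
            "error_gradient": None if np.isnan(grad) else float(grad),
            "stable": bool(stable),
            "error_flat": bool(flat),
            "qualifies": bool(stable and flat),
        })
    qualifying = [c["k"] for c in candidates if c["qualifies"]]
    if qualifying:
        selected = qualifying[0]
        no_elbow = False
    else:
        selected = int(curve.k_grid[0])
        no_elbow = True
    report = {
        "selected_k": selected,
        "no_elbow": no_elbow,
        "stability_floor": stability_floor,
        "error_gain_floor": error_gain_floor,
        "candidates": candidates,
    }
    return selected, report
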