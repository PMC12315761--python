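"""Multi-site batch-effect harmonization.

Implements the two-stage covariance batch correction used for pooled
multi-scanner morphometry: a per-row location-scale adjustment with
parametric empirical-Bayes shrinkage of batch parameters (the classic
ComBat model: normal prior on location shifts, inverse-gamma prior on scale
factors), followed by a covariance stage that applies the same
location-scale correction to principal-component scores of the adjusted
residuals (CovBat).  Covariate effects (age, sex, group, ...) are estimated
jointly and restored after adjustment, so biological variability is
preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class HarmonizationModel:
    """Fitted batch-correction parameters for one location-scale pass."""

    batches: list
    beta: np.ndarray            # rows x (n_batch + n_cov) full-design coefficients
    stand_mean: np.ndarray      # rows (pooled intercept)
    var_pooled: np.ndarray      # rows
    gamma_star: dict            # batch -> per-row location shift
    delta_star: dict            # batch -> per-row scale factor (variance)
    eb: bool
    pc_basis: np.ndarray = None
    pc_fraction: float = None
    pc_varfrac: np.ndarray = None

    def to_json(self) -> str:
        d = {
            "batches": [str(b) for b in self.batches],
            "eb": self.eb,
            "pc_fraction": self.pc_fraction,
            "gamma_star": {str(b): v.tolist() for b, v in self.gamma_star.items()},
            "delta_star": {str(b): v.tolist() for b, v in self.delta_star.items()},
            "stand_mean": self.stand_mean.tolist(),
            "var_pooled": self.var_pooled.tolist(),
        }
        return json.dumps(d)


def _as_design(covariates, n) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    Z = np.asarray(covariates, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError("covariate rows must match subject count")
    return Z


def _eb_fit(gamma_hat, delta_hat, z, members, conv=1e-4, max_iter=1000):
    """Parametric empirical-Bayes posterior for one batch (all rows jointly).

    Normal prior on gamma, inverse-gamma prior on delta^2, hyperparameters
    by method of moments; the coupled posteriors are solved by fixed-point
    iteration.
    """
    n_i = members.size
    g_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1)
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    if t2 <= 0 or s2 <= 0:  # degenerate across-row moments: nothing to shrink
        return gamma_hat, delta_hat
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    zb = z[:, members]
    for _ in range(max_iter):
        g_new = (t2 * n_i * gamma_hat + d_old * g_bar) / (t2 * n_i + d_old)
        sum2 = ((zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n_i / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(data, batch, covariates=None, eb: bool = True):
    """Per-row location-scale batch adjustment (ComBat).

    Parameters
    ----------
    data : (rows, subjects) array
    batch : length-subjects labels (2+ levels; a single level is a no-op)
    covariates : (subjects, p) design whose effects are preserved
    eb : shrink per-row batch parameters with parametric empirical Bayes;
        ``False`` uses the raw per-row moment estimates.

    Returns ``(adjusted, model)``.
    """
    X = np.asarray(data, float)
    if X.ndim == 1:
        X = X[None, :]
    G, n = X.shape
    batch = np.asarray(batch)
    levels = list(pd_unique(batch))
    counts = {b: int((batch == b).sum()) for b in levels}
    if len(levels) == 1:
        model = HarmonizationModel(
            batches=levels, beta=None, stand_mean=X.mean(axis=1),
            var_pooled=X.var(axis=1), gamma_star={levels[0]: np.zeros(G)},
            delta_star={levels[0]: np.ones(G)}, eb=eb,
        )
        return X.copy(), model
    for b, c in counts.items():
        if c < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 subjects")

    B = np.column_stack([(batch == b).astype(float) for b in levels])
    Z = _as_design(covariates, n)
    D = np.column_stack([B, Z])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient design (batch indicators + covariates)")

    beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)  # (n_batch + p) x G
    n_b = len(levels)
    frac = np.array([counts[b] / n for b in levels])
    grand_mean = frac @ beta[:n_b]          # per row
    fit_full = (D @ beta).T                  # G x n
    var_pooled = ((X - fit_full) ** 2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    cov_effect = (Z @ beta[n_b:]).T if Z.shape[1] else np.zeros((G, n))
    stand = grand_mean[:, None] + cov_effect
    z = (X - stand) / np.sqrt(var_pooled)[:, None]

    gamma_star, delta_star = {}, {}
    for b in levels:
        members = np.flatnonzero(batch == b)
        g_hat = z[:, members].mean(axis=1)
        # population variance, matching var_pooled's 1/n convention: two
        # identical batches then get scale factors of exactly 1
        d_hat = z[:, members].var(axis=1)
        d_hat = np.where(d_hat <= 0, 1e-12, d_hat)
        if eb and G >= 2:
            g_star, d_star = _eb_fit(g_hat, d_hat, z, members)
        else:
            g_star, d_star = g_hat, d_hat
        gamma_star[b], delta_star[b] = g_star, d_star

    adjusted = np.empty_like(X)
    for b in levels:
        members = np.flatnonzero(batch == b)
        adjusted[:, members] = (
            (z[:, members] - gamma_star[b][:, None])
            / np.sqrt(delta_star[b])[:, None]
        )
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand

    model = HarmonizationModel(
        batches=levels, beta=beta, stand_mean=grand_mean,
        var_pooled=var_pooled, gamma_star=gamma_star,
        delta_star=delta_star, eb=eb,
    )
    return adjusted, model


def pd_unique(values):
    """First-occurrence unique levels (stable, unlike np.unique)."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def stack_tables(tables: dict):
    """Vertically stack named row-blocks; returns (matrix, slices)."""
    keys = list(tables)
    mats = []
    slices = {}
    row = 0
    n_cols = None
    for k in keys:
        M = np.asarray(tables[k], float)
        if M.ndim == 1:
            M = M[None, :]
        if n_cols is None:
            n_cols = M.shape[1]
        elif M.shape[1] != n_cols:
            raise ValueError(f"table {k!r} has {M.shape[1]} subjects, expected {n_cols}")
        slices[k] = slice(row, row + M.shape[0])
        row += M.shape[0]
        mats.append(M)
    return np.vstack(mats), slices


def unstack_tables(matrix, slices: dict) -> dict:
    return {k: matrix[s] for k, s in slices.items()}


def covbat_adjust(tables: dict, batch, covariates=None,
                  pc_fraction: float = 0.95, eb: bool = True):
    """Covariance-aware harmonization of stacked feature tables.

    The named tables (e.g. vertex-wise thickness, area, gyrification plus a
    one-row total-volume scalar) are stacked vertically, location-scale
    adjusted, and the principal-component scores of the adjusted residuals
    spanning ``pc_fraction`` of the variance are themselves location-scale
    adjusted across batches before reconstruction, removing batch effects
    from the combined covariance.  Covariate effects are restored.

    Returns ``(harmonized tables dict, HarmonizationModel)``.
    """
    if not (0 < pc_fraction <= 1):
        raise ValueError(f"pc_fraction must be in (0, 1], got {pc_fraction}")
    stacked, slices = stack_tables(tables)
    adjusted, model = combat_adjust(stacked, batch, covariates, eb=eb)
    batch = np.asarray(batch)
    if len(model.batches) == 1:
        return unstack_tables(adjusted, slices), model

    n = stacked.shape[1]
    Z = _as_design(covariates, n)
    D = np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(D, adjusted.T, rcond=None)
    fitted = (D @ beta).T
    resid = adjusted - fitted

    # principal axes of the adjusted residuals (subjects are observations)
    U, S, Vt = np.linalg.svd(resid, full_matrices=False)
    varfrac = S**2 / (S**2).sum()
    q = int(np.searchsorted(np.cumsum(varfrac), pc_fraction) + 1)
    q = min(q, S.size)
    scores = U.T @ resid  # all-component scores, rows = PCs

    adj_scores, _ = combat_adjust(scores[:q], batch, covariates=None, eb=False)
    resid_new = resid + U[:, :q] @ (adj_scores - scores[:q])
    harmonized = resid_new + fitted

    model.pc_basis = U[:, :q]
    model.pc_fraction = pc_fraction
    model.pc_varfrac = varfrac
    return unstack_tables(harmonized, slices), model
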