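"""Behavioral partial least squares correlation (bPLS).

SVD of the cross-block correlation matrix between a brain block (subject x
component-metric factorization weights) and a behaviour block (group, age,
sex, lesion status, maternal education and the 12 executive-function
scales).  Each singular triplet is one latent variable (LV): a brain
salience pattern, a behaviour salience pattern, and a singular value whose
squared share of the total is the LV's covariance explained.  Inference is
fully resampling-based: permutation p-values for singular values, bootstrap
ratios and percentile CIs for saliences (each resample order/sign-aligned
to the original solution), and a split-half reproducibility test of the
left and right singular vectors against a permuted null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .simulate import BRIEF_SCALES, METRICS

BEHAVIOR_COLUMNS = ["group", "age", "sex", "lesion", "maternal_education"] + BRIEF_SCALES


class PreprocessingError(ValueError):
    pass


@dataclass
class BrainBlock:
    X: np.ndarray                # subjects x (k * n_metrics), z-scored
    column_labels: list          # (component, metric)
    subject_ids: list


@dataclass
class BehaviorBlock:
    Y: np.ndarray                # subjects x 17, z-scored
    column_labels: list
    subject_ids: list


@dataclass
class PlsResult:
    singular_values: np.ndarray
    brain_saliences: np.ndarray      # (k * n_metrics) x L
    behavior_saliences: np.ndarray   # 17 x L
    varexp: np.ndarray               # s^2 / sum s^2
    x_scores: np.ndarray
    y_scores: np.ndarray
    brain_labels: list = None
    behavior_labels: list = None
    perm_p: np.ndarray = None
    bootstrap_ratios_brain: np.ndarray = None
    bootstrap_ratios_behavior: np.ndarray = None
    ci95_brain: np.ndarray = None          # (..., 2) lo/hi
    ci95_behavior: np.ndarray = None
    contributing_brain: np.ndarray = None
    contributing_behavior: np.ndarray = None
    splithalf_p_left: np.ndarray = None    # brain side, per LV
    splithalf_p_right: np.ndarray = None   # behaviour side, per LV
    n_redrawn_resamples: int = 0

    @property
    def n_lv(self) -> int:
        return self.singular_values.size


def zscore_columns(M, names=None, ddof: int = 1):
    M = np.asarray(M, float)
    sd = M.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise PreprocessingError(f"zero-variance column: {label}")
    return (M - M.mean(axis=0)) / sd


def build_design_matrices(cohort: pd.DataFrame, H: np.ndarray,
                          h_column_labels: list, metric_order=METRICS):
    """Assemble the z-scored brain and behaviour blocks.

    ``H`` is the k x (subjects * metrics) weight matrix and
    ``h_column_labels`` its per-column (subject_id, metric) provenance.
    Subjects with any missing behaviour value are dropped listwise (ids
    returned for the log).  Returns ``(BrainBlock, BehaviorBlock, dropped)``.
    """
    k = H.shape[0]
    col_of = {lab: j for j, lab in enumerate(h_column_labels)}
    subjects = list(cohort["subject_id"])
    missing = [s for s in subjects if (s, metric_order[0]) not in col_of]
    if missing:
        raise ValueError(f"subjects absent from factorization weights: {missing[:5]}")

    beh = cohort.set_index("subject_id")[BEHAVIOR_COLUMNS]
    dropped = list(beh.index[beh.isna().any(axis=1)])
    kept = [s for s in subjects if s not in set(dropped)]
    if len(kept) < 3:
        raise ValueError("fewer than 3 subjects with complete behaviour data")

    X = np.empty((len(kept), k * len(metric_order)))
    labels = []
    for b, m in enumerate(metric_order):
        for c in range(k):
            labels.append((c, m))
    for i, s in enumerate(kept):
        X[i] = np.concatenate([H[:, col_of[(s, m)]] for m in metric_order])
    Y = beh.loc[kept].to_numpy(float)

    brain = BrainBlock(zscore_columns(X, labels), labels, kept)
    behavior = BehaviorBlock(zscore_columns(Y, BEHAVIOR_COLUMNS),
                             BEHAVIOR_COLUMNS, kept)
    return brain, behavior, dropped


def _cross_correlation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return Y.T @ X / (X.shape[0] - 1)


def _svd_oriented(R: np.ndarray):
    """SVD with the deterministic sign convention.

    Each LV's behaviour salience vector is oriented so its largest-magnitude
    entry is positive; the paired brain salience flips with it.
    """
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for l in range(S.size):
        j = int(np.argmax(np.abs(U[:, l])))
        if U[j, l] < 0:
            U[:, l] *= -1.0
            V[:, l] *= -1.0
    return U, S, V


def fit_bpls(X: np.ndarray, Y: np.ndarray, brain_labels=None,
             behavior_labels=None) -> PlsResult:
    """Fit the PLS correlation model on z-scored blocks."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks disagree in subject count")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    for M, names in ((X, brain_labels), (Y, behavior_labels)):
        sd = M.std(axis=0, ddof=1)
        if (sd == 0).any():
            j = int(np.flatnonzero(sd == 0)[0])
            label = names[j] if names is not None else f"column {j}"
            raise PreprocessingError(f"zero-variance column: {label}")
    R = _cross_correlation(X, Y)
    U, S, V = _svd_oriented(R)
    return PlsResult(
        singular_values=S,
        brain_saliences=V,
        behavior_saliences=U,
        varexp=S**2 / (S**2).sum(),
        x_scores=X @ V,
        y_scores=Y @ U,
        brain_labels=brain_labels,
        behavior_labels=behavior_labels,
    )


def latent_scores(X: np.ndarray, Y: np.ndarray, result: PlsResult):
    """Subject-level LV expressions: ``(X V, Y U)``, row order preserved."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[1] != result.brain_saliences.shape[0]:
        raise ValueError("X width does not match brain saliences")
    if Y.shape[1] != result.behavior_saliences.shape[0]:
        raise ValueError("Y width does not match behaviour saliences")
    return X @ result.brain_saliences, Y @ result.behavior_saliences


def permutation_pvalues(X: np.ndarray, Y: np.ndarray, n_perm: int = 10_000,
                        seed: int = 0) -> np.ndarray:
    """Add-one permutation p per LV singular value (rows of Y permuted)."""
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] < 10:
        warnings.warn("fewer than 10 subjects: permutation test is underpowered")
    rng = np.random.default_rng(seed)
    s_obs = np.linalg.svd(_cross_correlation(X, Y), compute_uv=False)
    exceed = np.zeros_like(s_obs)
    n = X.shape[0]
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        s = np.linalg.svd(_cross_correlation(X, Yp), compute_uv=False)
        exceed += s >= s_obs
    return (1.0 + exceed) / (1.0 + n_perm)


def _rezscore(M: np.ndarray):
    sd = M.std(axis=0, ddof=1)
    if (sd == 0).any():
        return None
    return (M - M.mean(axis=0)) / sd


def bootstrap_saliences(X: np.ndarray, Y: np.ndarray, n_boot: int = 10_000,
                        seed: int = 0, result: PlsResult = None,
                        resampler=None) -> PlsResult:
    """Bootstrap the saliences; fills the bootstrap fields of the result.

    Subjects are resampled with replacement and the model refitted on the
    re-standardized resample; each resample's singular vectors are aligned
    to the original by optimal order/sign matching (Hungarian assignment on
    the stacked behaviour+brain similarity, so both sides share one
    alignment).  A free orthogonal rotation was rejected here: it lets
    noise latent variables rotate into the leading ones and shrinks the
    bootstrap variability of near-zero saliences well below their true
    sampling variability, over-flagging null variables.  Bootstrap ratio =
    original salience / bootstrap SD; 95% CI = 2.5/97.5 percentiles; a
    variable contributes when its CI excludes zero.  Resamples with a
    constant column are redrawn (count kept on the result).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    res = fit_bpls(X, Y) if result is None else result
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boots_U = np.empty((n_boot, *res.behavior_saliences.shape))
    boots_V = np.empty((n_boot, *res.brain_saliences.shape))
    if resampler is None:
        resampler = lambda rng, n: rng.integers(0, n, size=n)  # noqa: E731
    redrawn = 0
    for b in range(n_boot):
        for _attempt in range(100):
            idx = resampler(rng, n)
            Xb, Yb = _rezscore(X[idx]), _rezscore(Y[idx])
            if Xb is not None and Yb is not None:
                break
            redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        Ub, Sb, Vb = _svd_oriented(_cross_correlation(Xb, Yb))
        boots_U[b], boots_V[b] = _align_to_reference(
            Ub, Vb, res.behavior_saliences, res.brain_saliences
        )

    def summarize(orig, boots):
        sd = boots.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        ratio = orig / sd
        ci = np.stack(
            [np.percentile(boots, 2.5, axis=0), np.percentile(boots, 97.5, axis=0)],
            axis=-1,
        )
        contributing = (ci[..., 0] > 0) | (ci[..., 1] < 0)
        return ratio, ci, contributing

    (res.bootstrap_ratios_behavior, res.ci95_behavior,
     res.contributing_behavior) = summarize(res.behavior_saliences, boots_U)
    (res.bootstrap_ratios_brain, res.ci95_brain,
     res.contributing_brain) = summarize(res.brain_saliences, boots_V)
    res.n_redrawn_resamples = redrawn
    return res


def _align_to_reference(U_h, V_h, U_ref, V_ref):
    """Order- and sign-align one half's singular vectors to the reference."""
    A = np.vstack([U_h, V_h])
    B = np.vstack([U_ref, V_ref])
    C = A.T @ B  # similarity between half vectors and reference vectors
    rows, cols = linear_sum_assignment(-np.abs(C))
    order = np.empty(C.shape[1], dtype=int)
    order[cols] = rows
    signs = np.sign(C[order, np.arange(C.shape[1])])
    signs[signs == 0] = 1.0
    return U_h[:, order] * signs, V_h[:, order] * signs


def _corr_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    num = (Ac * Bc).sum(axis=0)
    den = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    den[den == 0] = np.inf
    return num / den


def split_half_singular_stability(X: np.ndarray, Y: np.ndarray,
                                  n_splits: int = 200, n_perm: int = 500,
                                  seed: int = 0):
    """Split-half reproducibility p-values for each LV, per side.

    Subjects are repeatedly split into random halves; each half's
    cross-block correlation is decomposed and its singular vectors are
    order/sign-aligned to the full-sample solution; the statistic per LV is
    the mean over splits of the correlation between the two halves' aligned
    vectors (left = brain side, right = behaviour side).  The null
    distribution re-runs the same splits after permuting the rows of Y.
    Returns ``(p_left, p_right)`` (add-one estimators).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    if n < 8:
        raise ValueError("split-half stability needs at least 8 subjects")
    rng = np.random.default_rng(seed)
    splits = [rng.permutation(n) for _ in range(n_splits)]
    half = n // 2

    def statistic(Ymat):
        U_ref, _, V_ref = _svd_oriented(_cross_correlation(X, Ymat))
        L = U_ref.shape[1]
        acc_left = np.zeros(L)
        acc_right = np.zeros(L)
        used = 0
        for perm in splits:
            ia, ib = perm[:half], perm[half:]
            Xa, Ya = _rezscore(X[ia]), _rezscore(Ymat[ia])
            Xb, Yb = _rezscore(X[ib]), _rezscore(Ymat[ib])
            if Xa is None or Ya is None or Xb is None or Yb is None:
                continue
            Ua, _, Va = _svd_oriented(_cross_correlation(Xa, Ya))
            Ub, _, Vb = _svd_oriented(_cross_correlation(Xb, Yb))
            Ua, Va = _align_to_reference(Ua, Va, U_ref, V_ref)
            Ub, Vb = _align_to_reference(Ub, Vb, U_ref, V_ref)
            acc_left += _corr_cols(Va, Vb)
            acc_right += _corr_cols(Ua, Ub)
            used += 1
        if used == 0:
            raise RuntimeError("every split produced a degenerate half")
        return acc_left / used, acc_right / used

    obs_left, obs_right = statistic(Y)
    exceed_left = np.zeros_like(obs_left)
    exceed_right = np.zeros_like(obs_right)
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        nl, nr = statistic(Yp)
        exceed_left += nl >= obs_left
        exceed_right += nr >= obs_right
    p_left = (1.0 + exceed_left) / (1.0 + n_perm)
    p_right = (1.0 + exceed_right) / (1.0 + n_perm)
    return p_left, p_right


def results_tables(res: PlsResult):
    """Export the fitted model as tidy tables (lv_summary, saliences,
    scores, bootstrap)."""
    L = res.n_lv
    lv = pd.DataFrame({
        "lv": np.arange(1, L + 1),
        "singular_value": res.singular_values,
        "varexp": res.varexp,
    })
    if res.perm_p is not None:
        lv["perm_p"] = res.perm_p
    if res.splithalf_p_left is not None:
        lv["splithalf_p_left"] = res.splithalf_p_left
        lv["splithalf_p_right"] = res.splithalf_p_right

    rows = []
    for side, sal, labels, ratios, ci, contrib in (
        ("brain", res.brain_saliences, res.brain_labels,
         res.bootstrap_ratios_brain, res.ci95_brain, res.contributing_brain),
        ("behavior", res.behavior_saliences, res.behavior_labels,
         res.bootstrap_ratios_behavior, res.ci95_behavior,
         res.contributing_behavior),
    ):
        for i in range(sal.shape[0]):
            name = labels[i] if labels is not None else i
            for l in range(L):
                row = {"side": side, "variable": str(name), "lv": l + 1,
                       "salience": sal[i, l]}
                if ratios is not None:
                    row.update(bootstrap_ratio=ratios[i, l],
                               ci_lo=ci[i, l, 0], ci_hi=ci[i, l, 1],
                               contributing=bool(contrib[i, l]))
                rows.append(row)
    saliences = pd.DataFrame(rows)

    scores = pd.DataFrame(
        np.hstack([res.x_scores, res.y_scores]),
        columns=[f"x_score_lv{l+1}" for l in range(L)]
        + [f"y_score_lv{l+1}" for l in range(L)],
    )
    return lv, saliences, scores
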