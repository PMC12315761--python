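"""Control matching, abnormality flagging and descriptive group statistics.

Covers the cohort-characterisation stage of a case-control morphometry
study: 1:1 nearest-neighbour matching of controls to cases on age and sex,
clinical-abnormality flagging of executive-function T-scores (T >= 65),
contingency-table tests (Pearson chi-square / Fisher exact), and covariate-
adjusted group comparisons (ANCOVA with Mann-Whitney or log-transform
fallbacks when residuals are non-normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MatchResult:
    pairs: list  # (case_id, control_id, distance)
    unmatched_controls: list

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id", "distance"])

    @property
    def matched_ids(self) -> list:
        return [cid for pair in self.pairs for cid in pair[:2]]


@dataclass
class GroupTestResult:
    test_name: str  # ancova | log_ancova | mann_whitney | chi_square | fisher_exact
    statistic: float
    df: tuple
    p_value: float
    n_used: int

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def match_controls(cohort: pd.DataFrame, covariates=("age", "sex")) -> MatchResult:
    """1:1 greedy nearest-neighbour matching of controls to cases.

    Distance is raw-scale Euclidean over ``covariates``; cases are processed
    in table order and each consumes its nearest remaining control, ties
    broken by first occurrence.  Deterministic.
    """
    cases = cohort[cohort["group"] == 1]
    controls = cohort[cohort["group"] == 0]
    if len(controls) < len(cases):
        raise ValueError(
            f"cannot match {len(cases)} cases with only {len(controls)} controls"
        )
    Xca = cases[list(covariates)].to_numpy(float)
    Xco = controls[list(covariates)].to_numpy(float)
    control_ids = controls["subject_id"].to_list()
    available = np.ones(len(controls), dtype=bool)
    pairs = []
    for i, cid in enumerate(cases["subject_id"]):
        d = np.sqrt(((Xco - Xca[i]) ** 2).sum(axis=1))
        d[~available] = np.inf
        j = int(np.argmin(d))  # argmin takes the first minimum: tie rule
        pairs.append((cid, control_ids[j], float(d[j])))
        available[j] = False
    return MatchResult(
        pairs=pairs,
        unmatched_controls=[control_ids[j] for j in np.flatnonzero(available)],
    )


def flag_abnormal(t_scores, cutoff: float = 65.0):
    """Flag clinically abnormal T-scores (T >= cutoff, inclusive).

    Returns ``(flags, proportion)``; the proportion is over non-missing
    values and NaN flags stay missing.
    """
    t = np.asarray(t_scores, float)
    valid = ~np.isnan(t)
    if not valid.any():
        raise ValueError("cannot compute an abnormality proportion of all-missing scores")
    flags = np.where(valid, t >= cutoff, np.nan)
    proportion = float(np.nansum(flags) / valid.sum())
    return flags, proportion


def compare_proportions(a: int, b: int, c: int, d: int,
                        method: str = "auto") -> GroupTestResult:
    """Two-group proportion test on the 2x2 table [[a, b], [c, d]].

    ``method="auto"`` runs the Fisher exact test (two-sided,
    minimum-likelihood convention: sum of table probabilities <= the
    observed table's) when any expected count is below 5, and the Pearson
    chi-square without continuity correction otherwise.  ``"fisher"`` or
    ``"chi2"`` force a branch.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any() or not np.all(counts == counts.astype(int)):
        raise ValueError("counts must be non-negative integers")
    if counts.sum(axis=0).min() <= 0 or counts.sum(axis=1).min() <= 0:
        raise ValueError("both table margins must be positive")
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    if method == "auto":
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "fisher":
        res = stats.fisher_exact(counts.astype(int), alternative="two-sided")
        return GroupTestResult("fisher_exact", float(res.statistic), None,
                               float(res.pvalue), int(n))
    if method == "chi2":
        res = stats.chi2_contingency(counts, correction=False)
        return GroupTestResult("chi_square", float(res.statistic), (1,),
                               float(res.pvalue), int(n))
    raise ValueError(f"unknown method {method!r}")


def _design(covariates: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    return X


def _check_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design over columns {list(names)}")


def ancova_group_test(outcome, group, covariates: pd.DataFrame) -> GroupTestResult:
    """F-test for a binary group effect adjusted for covariates.

    Compares the full least-squares fit (intercept + group + covariates)
    against the reduced fit (intercept + covariates); for a single binary
    factor this equals the Type III test.  Returns F with (1, n - p) df.
    """
    y = np.asarray(outcome, float)
    g = np.asarray(group, float)
    keep = ~np.isnan(y)
    if covariates is not None and len(covariates.columns):
        keep &= ~covariates.isna().any(axis=1).to_numpy()
        Z = covariates.loc[keep]
    else:
        Z = pd.DataFrame(index=np.flatnonzero(keep))
    y, g = y[keep], g[keep]
    n = y.size
    X_red = _design(Z) if len(Z.columns) else np.ones((n, 1))
    X_full = np.column_stack([X_red, g])
    names = ["intercept", *Z.columns, "group"]
    if n <= X_full.shape[1]:
        raise ValueError("more model parameters than observations")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome")
    _check_rank(X_full, names)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full, rss_red = rss(X_full), rss(X_red)
    df2 = n - X_full.shape[1]
    F = (rss_red - rss_full) / (rss_full / df2)
    p = float(stats.f.sf(F, 1, df2))
    return GroupTestResult("ancova", float(F), (1, df2), p, n)


def compare_groups_continuous(outcome, group, covariates: pd.DataFrame = None,
                              strategy: str = "auto",
                              alpha: float = 0.05) -> GroupTestResult:
    """Covariate-adjusted group comparison with non-normality fallbacks.

    Strategies: ``ancova``, ``log_ancova`` (outcome log-transformed, requires
    positive values), ``mann_whitney`` (two-sided, unadjusted), or ``auto``:
    run the ANCOVA, Shapiro-Wilk its residuals at ``alpha``; if non-normal
    and the outcome is positive, try the log branch, else fall back to
    Mann-Whitney.  The returned ``test_name`` records the branch taken.
    """
    y = np.asarray(outcome, float)
    g = np.asarray(group, float)
    if np.unique(g[~np.isnan(y)]).size < 2:
        raise ValueError("need two non-empty groups")

    mask = ~np.isnan(y)
    cov_arr = (covariates.to_numpy(float)[mask]
               if covariates is not None and len(covariates.columns) else None)

    def _residuals_normal(yv):
        cols = [np.ones(yv.size), g[mask]]
        if cov_arr is not None:
            cols.append(cov_arr)
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        return stats.shapiro(resid).pvalue >= alpha

    if strategy == "auto":
        yv = y[mask]
        if _residuals_normal(yv):
            strategy = "ancova"
        elif (yv > 0).all() and _residuals_normal(np.log(yv)):
            strategy = "log_ancova"
        else:
            strategy = "mann_whitney"

    if strategy == "ancova":
        return ancova_group_test(y, g, covariates)
    if strategy == "log_ancova":
        if np.nanmin(y) <= 0:
            raise ValueError("log transform requires strictly positive outcome")
        res = ancova_group_test(np.log(y), g, covariates)
        return GroupTestResult("log_ancova", res.statistic, res.df,
                               res.p_value, res.n_used)
    if strategy == "mann_whitney":
        x0 = y[(g == 0) & ~np.isnan(y)]
        x1 = y[(g == 1) & ~np.isnan(y)]
        res = stats.mannwhitneyu(x1, x0, alternative="two-sided")
        return GroupTestResult("mann_whitney", float(res.statistic), None,
                               float(res.pvalue), x0.size + x1.size)
    raise ValueError(f"unknown strategy {strategy!r}")


def group_comparison_table(cohort: pd.DataFrame, outcomes,
                           covariate_cols=("age", "sex", "maternal_education"),
                           strategy: str = "auto") -> pd.DataFrame:
    """Tidy per-outcome group-comparison table (one row per outcome)."""
    rows = []
    cov = cohort[list(covariate_cols)] if covariate_cols else None
    for col in outcomes:
        res = compare_groups_continuous(cohort[col], cohort["group"], cov,
                                        strategy=strategy)
        rows.append({
            "outcome": col, "test_name": res.test_name,
            "statistic": res.statistic,
            "df": "" if res.df is None else "/".join(str(d) for d in res.df),
            "p": res.p_value, "n": res.n_used,
        })
    return pd.DataFrame(rows)
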