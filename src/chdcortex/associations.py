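"""Exploratory Spearman associations between LV scores and clinical variables.

Computed within the case group only (the clinical variables — age at first
open-heart surgery, total aortic cross-clamp time — exist only for cases).
Average-rank Spearman rho with the t-distribution p-value; an exact
permutation p is available for very small samples.  Missing pairs are
dropped pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    variable: str
    score_kind: str  # "brain" | "behavior"
    lv_index: int
    rho: float
    p: float
    n: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")


def spearman_assoc(scores, clinical, variable: str = "", score_kind: str = "brain",
                   lv_index: int = 1, group_filter=None,
                   method: str = "t") -> AssociationResult:
    """Spearman rank correlation between per-subject scores and a clinical
    variable.

    ``group_filter`` (boolean per subject) restricts to the case group;
    pairs with a missing value on either side are dropped.  ``method="t"``
    uses the t-approximation p-value; ``"exact"`` enumerates all rank
    permutations (only sensible for n < 10).
    """
    s = np.asarray(scores, float)
    c = np.asarray(clinical, float)
    if group_filter is not None:
        keep = np.asarray(group_filter, bool)
        s, c = s[keep], c[keep]
    valid = ~(np.isnan(s) | np.isnan(c))
    s, c = s[valid], c[valid]
    n = s.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, have {n}")
    if np.ptp(s) == 0 or np.ptp(c) == 0:
        raise ValueError("constant vector after filtering: correlation undefined")

    rho, p_t = stats.spearmanr(s, c)
    if method == "exact":
        rs = stats.rankdata(s)
        rc = stats.rankdata(c)
        obs = abs(np.corrcoef(rs, rc)[0, 1])
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = abs(np.corrcoef(rs, rc[list(perm)])[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    else:
        p = float(p_t)
    return AssociationResult(variable=variable, score_kind=score_kind,
                             lv_index=lv_index, rho=float(rho), p=p, n=n)


def association_table(cohort: pd.DataFrame, x_scores, y_scores,
                      clinical_cols=("age_first_surgery", "cross_clamp_time"),
                      lv_indices=(1,)) -> pd.DataFrame:
    """Tidy association table over clinical variables and LV score kinds."""
    case = (cohort["group"] == 1).to_numpy()
    rows = []
    for var in clinical_cols:
        clin = cohort[var].to_numpy(float)
        for lv in lv_indices:
            for kind, scores in (("brain", x_scores), ("behavior", y_scores)):
                res = spearman_assoc(scores[:, lv - 1], clin, variable=var,
                                     score_kind=kind, lv_index=lv,
                                     group_filter=case)
                rows.append({"variable": var, "score_kind": kind, "lv_index": lv,
                             "rho": res.rho, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
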