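"""Exploratory clinical associations within the case group.

Correlates each subject's expression of the first latent variable (brain
x-scores and behaviour y-scores) with age at first surgery and total aortic
cross-clamp time, case group only, Spearman rank correlation with pairwise
deletion of missing values.
"""

from pathlib import Path

import pandas as pd

import chdcortex as cc

ROOT = Path(__file__).resolve().parents[1]


def main():
    (ROOT / "results").mkdir(exist_ok=True)
    cohort, _ = cc.read_dataset(ROOT / "scratch" / "harmonized",
                                validate=False)
    scores = pd.read_csv(ROOT / "results" / "scores.csv")
    cohort = cohort.set_index("subject_id").loc[
        scores["subject_id"]].reset_index()
    x_cols = [c for c in scores.columns if c.startswith("x_score")]
    y_cols = [c for c in scores.columns if c.startswith("y_score")]

    table = cc.association_table(
        cohort, scores[x_cols].to_numpy(), scores[y_cols].to_numpy(),
        lv_indices=(1,),
    )
    table.to_csv(ROOT / "results" / "associations.csv", index=False)
    for _, row in table.iterrows():
        print(f"LV{row.lv_index} {row.score_kind:8s} ~ {row.variable}: "
              f"rho = {row.rho:+.2f}, p = {row.p:.3g} (n = {row.n})")


if __name__ == "__main__":
    main()
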