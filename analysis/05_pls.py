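"""Behavioural PLS linking factorization weights to participant measures.

Builds the subject x (component, metric) brain block from the fitted
weights and the 17-column behaviour block (group, age, sex, lesion,
maternal education, 12 executive-function scales), fits the PLS correlation
model, and runs the three inference layers: permutation p per latent
variable, bootstrap ratios/CIs per salience, split-half reproducibility per
side.  Tables go to results/.
"""

from pathlib import Path

import numpy as np

import chdcortex as cc
from chdcortex.pls import results_tables

ROOT = Path(__file__).resolve().parents[1]
SEED = 910


def main():
    (ROOT / "results").mkdir(exist_ok=True)
    cohort, _ = cc.read_dataset(ROOT / "scratch" / "harmonized",
                                validate=False)
    H = np.loadtxt(ROOT / "results" / "H.tsv")
    import json
    labels = [tuple(l) for l in json.loads(
        (ROOT / "results" / "opnmf_columns.json").read_text())]

    brain, behavior, dropped = cc.build_design_matrices(cohort, H, labels)
    if dropped:
        print(f"dropped {len(dropped)} subjects with incomplete behaviour data")

    res = cc.fit_bpls(brain.X, behavior.Y, brain.column_labels,
                      behavior.column_labels)
    res.perm_p = cc.permutation_pvalues(brain.X, behavior.Y, n_perm=2000,
                                        seed=SEED)
    res = cc.bootstrap_saliences(brain.X, behavior.Y, n_boot=2000,
                                 seed=SEED + 1, result=res)
    res.splithalf_p_left, res.splithalf_p_right = \
        cc.split_half_singular_stability(brain.X, behavior.Y, n_splits=100,
                                         n_perm=200, seed=SEED + 2)

    lv, sal, scores = results_tables(res)
    lv.to_csv(ROOT / "results" / "lv_summary.csv", index=False)
    sal.to_csv(ROOT / "results" / "saliences.csv", index=False)
    scores.insert(0, "subject_id", brain.subject_ids)
    scores.to_csv(ROOT / "results" / "scores.csv", index=False)

    for l in range(min(3, res.n_lv)):
        contrib = [behavior.column_labels[i]
                   for i in np.flatnonzero(res.contributing_behavior[:, l])]
        print(f"LV{l+1}: {100*res.varexp[l]:.1f}% of covariance, "
              f"perm p = {res.perm_p[l]:.4g}, split-half p "
              f"(brain/behaviour) = {res.splithalf_p_left[l]:.3g}/"
              f"{res.splithalf_p_right[l]:.3g}")
        if contrib:
            print(f"     contributing behaviour variables: {', '.join(contrib)}")


if __name__ == "__main__":
    main()
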