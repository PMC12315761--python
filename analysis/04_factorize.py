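"""Rank selection and the final structural-covariance factorization.

Masks midline vertices, residualizes the harmonized features on total
grey-matter volume, builds the z-scored non-negative input matrix, runs the
split-half stability analysis over a candidate rank grid, then fits the
final factorization at the selected rank.  Curve, selection report, W/H and
the winner-take-all component map go to results/.
"""

import json
from pathlib import Path

import numpy as np

import chdcortex as cc

ROOT = Path(__file__).resolve().parents[1]
SEED = 77
K_GRID = range(2, 13)


def main():
    (ROOT / "results").mkdir(exist_ok=True)
    # harmonized features are residual-adjusted, so value-range validation
    # is not meaningful here
    cohort, features = cc.read_dataset(ROOT / "scratch" / "harmonized",
                                       validate=False)
    masked = cc.apply_midline_mask(features)
    volume = cohort["total_cgm_volume"].to_numpy(float)

    curve = cc.split_half_stability(masked.metrics, volume,
                                    masked.subject_order, K_GRID,
                                    n_splits=5, seed=SEED)
    curve.to_frame().to_csv(ROOT / "results" / "stability_curve.csv",
                            index=False)
    k, report = cc.select_k(curve)
    (ROOT / "results" / "k_selection.json").write_text(
        json.dumps(report, indent=1))
    i = list(K_GRID).index(k)
    print(f"selected k = {k} (mean split-half cosine "
          f"{curve.mean_similarity[i]:.3f}; no_elbow={report['no_elbow']})")

    resid = cc.residualize_on_volume(masked.metrics, volume)
    inp = cc.build_opnmf_input(resid, masked.subject_order)
    fit = cc.fit_opnmf(inp.V, k)
    rel = cc.reconstruction_error(inp.V, fit.W) / np.linalg.norm(inp.V)
    print(f"factorization: {fit.n_iter} iterations, converged={fit.converged}, "
          f"relative reconstruction error {rel:.3f}")

    np.savetxt(ROOT / "results" / "W.tsv", fit.W, fmt="%.6g", delimiter="\t")
    np.savetxt(ROOT / "results" / "H.tsv", fit.H, fmt="%.6g", delimiter="\t")
    (ROOT / "results" / "opnmf_columns.json").write_text(
        json.dumps([list(c) for c in inp.column_labels]))
    labels = cc.winner_take_all(fit.W)
    np.savetxt(ROOT / "results" / "component_labels.txt", labels, fmt="%d")
    sizes = np.bincount(labels[labels >= 0])
    print(f"winner-take-all parcel sizes: {sizes.tolist()}")


if __name__ == "__main__":
    main()
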