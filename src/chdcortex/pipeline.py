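"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the study design: simulate (or load) -> match controls
-> descriptive statistics -> harmonize across sites -> prepare the
factorization input -> split-half stability rank selection -> OPNMF ->
behavioural PLS with resampling inference -> clinical associations.  One
master seed is fanned out to per-stage seeds; for a fixed config + seed the
result bundle is bit-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import (BRIEF_SCALES, METRICS, SimulationSpec, simulate_cohort)
from .io import read_dataset, write_dataset
from .cohort import (compare_proportions, flag_abnormal, group_comparison_table,
                     match_controls)
from .harmonize import covbat_adjust
from .prep import apply_midline_mask, build_opnmf_input, residualize_on_volume
from .opnmf import fit_opnmf, winner_take_all
from .stability import select_k, split_half_stability
from .pls import (build_design_matrices, bootstrap_saliences, fit_bpls,
                  permutation_pvalues, results_tables,
                  split_half_singular_stability)
from .associations import association_table

ALL_STAGES = ("simulate", "match", "descriptives", "harmonize", "prep",
              "stability", "factorize", "pls", "associate")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    data_path: str = None              # load instead of simulate
    simulation: dict = field(default_factory=dict)  # SimulationSpec overrides
    # harmonization
    pc_fraction: float = 0.95
    eb: bool = True
    # rank selection / factorization
    k_grid: tuple = None
    k: int = None                      # fixed rank; skips selection if stability off
    max_iter: int = 100_000
    tol: float = 1e-5
    check_every: int = 10
    n_splits_stability: int = 10
    stability_floor: float = 0.8
    error_gain_floor: float = 0.01
    # PLS resampling
    n_perm: int = 10_000
    n_boot: int = 10_000
    n_splits_pls: int = 200
    n_perm_splithalf: int = 500
    abnormal_cutoff: float = 65.0

    def validate(self):
        required = ["outdir"]
        for name in required:
            if getattr(self, name) in (None, ""):
                raise ConfigError(f"missing config field: {name}")
        if "stability" in self.stages and self.k_grid is None:
            raise ConfigError("missing config field: k_grid")
        if "stability" not in self.stages and "factorize" in self.stages \
                and self.k is None and self.k_grid is None:
            raise ConfigError("missing config field: k (or k_grid)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["k_grid"] = None if self.k_grid is None else list(self.k_grid)
        # normalize for lossless YAML/JSON round-trips
        d["simulation"] = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in d["simulation"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if d.get("k_grid") is not None:
            d["k_grid"] = tuple(d["k_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage_seeds(master: int) -> dict:
    state = np.random.SeedSequence(master).generate_state(len(ALL_STAGES))
    return {s: int(v % (2**31)) for s, v in zip(ALL_STAGES, state)}


class StageFailure(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig, log=print):
    """Execute the enabled stages in order; returns a result dict.

    Writes per-stage tables under ``config.outdir`` plus ``manifest.json``
    (config, fanned-out seeds, package version, per-stage shapes and
    timings).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    cfg_dict = config.to_dict()
    cfg_dict["outdir"] = "."  # the bundle travels with its directory
    manifest = {
        "config": cfg_dict,
        "seeds": seeds,
        "version": __version__,
        "stages": {},
    }
    state = {}

    def record(stage, **info):
        manifest["stages"][stage] = info

    def enabled(stage):
        return stage in config.stages

    t0 = time.time()
    try:
        if enabled("simulate"):
            spec = SimulationSpec(**config.simulation)
            cohort, features, truth = simulate_cohort(spec, seed=seeds["simulate"])
            write_dataset(cohort, features, out / "dataset",
                          seed=seeds["simulate"], spec=spec)
            state.update(cohort=cohort, features=features, truth=truth)
            record("simulate", n_subjects=len(cohort),
                   n_vertices=features.geometry.n_vertices, k=spec.k)
            log(f"[simulate] {len(cohort)} subjects, "
                f"{features.geometry.n_vertices} vertices, k={spec.k}")
        elif config.data_path:
            cohort, features = read_dataset(config.data_path)
            state.update(cohort=cohort, features=features, truth=None)
            record("load", n_subjects=len(cohort))
    except Exception as e:  # noqa: BLE001
        raise StageFailure("simulate", e) from e

    cohort = state["cohort"]
    features = state["features"]

    def run_stage(name, fn):
        if not enabled(name):
            return
        t = time.time()
        try:
            fn()
        except Exception as e:  # noqa: BLE001
            raise StageFailure(name, e) from e
        manifest["stages"].setdefault(name, {})["seconds"] = round(time.time() - t, 3)
        log(f"[{name}] done in {time.time() - t:.1f}s")

    def _match():
        nonlocal cohort, features
        res = match_controls(cohort)
        res.as_frame().to_csv(out / "matching.csv", index=False)
        keep = set(res.matched_ids)
        sel = cohort["subject_id"].isin(keep).to_numpy()
        cohort = cohort.loc[sel].reset_index(drop=True)
        cols = np.flatnonzero(sel)
        from .simulate import VertexFeatureSet

        features = VertexFeatureSet(
            ct=features.ct[:, cols], sa=features.sa[:, cols],
            gi=features.gi[:, cols], geometry=features.geometry,
            subject_order=list(cohort["subject_id"]),
        )
        record("match", n_pairs=len(res.pairs),
               n_unmatched_controls=len(res.unmatched_controls))

    run_stage("match", _match)

    def _descriptives():
        table = group_comparison_table(cohort, BRIEF_SCALES)
        table.to_csv(out / "descriptives.csv", index=False)
        rows = []
        for s in BRIEF_SCALES:
            chd = cohort.loc[cohort["group"] == 1, s]
            ctl = cohort.loc[cohort["group"] == 0, s]
            fa, pa = flag_abnormal(chd, config.abnormal_cutoff)
            fb, pb = flag_abnormal(ctl, config.abnormal_cutoff)
            a, c = int(np.nansum(fa)), int(np.nansum(fb))
            na, nc = int(np.sum(~np.isnan(fa))), int(np.sum(~np.isnan(fb)))
            if 0 < a + c < na + nc:
                res = compare_proportions(a, na - a, c, nc - c)
                test, p = res.test_name, res.p_value
            else:  # nobody (or everybody) abnormal: no test to run
                test, p = "none", np.nan
            rows.append({"scale": s, "abnormal_chd": a, "n_chd": na,
                         "abnormal_control": c, "n_control": nc,
                         "prop_chd": pa, "prop_control": pb,
                         "test": test, "p": p})
        pd.DataFrame(rows).to_csv(out / "abnormal_proportions.csv", index=False)
        record("descriptives", n_outcomes=len(BRIEF_SCALES))

    run_stage("descriptives", _descriptives)

    harmonized = {m: getattr(features, m) for m in METRICS}
    volume = cohort["total_cgm_volume"].to_numpy(float)

    def _harmonize():
        nonlocal harmonized, volume
        covs = np.column_stack([
            cohort["age"].to_numpy(float),
            cohort["sex"].to_numpy(float),
            cohort["group"].to_numpy(float),
        ])
        tables = {m: getattr(features, m) for m in METRICS}
        tables["volume"] = volume[None, :]
        adj, model = covbat_adjust(tables, cohort["site"].to_numpy(),
                                   covariates=covs,
                                   pc_fraction=config.pc_fraction, eb=config.eb)
        harmonized = {m: adj[m] for m in METRICS}
        volume = np.clip(adj["volume"][0], 1.0, None)
        (out / "harmonization_model.json").write_text(model.to_json())
        record("harmonize", n_batches=len(model.batches),
               n_pcs=None if model.pc_basis is None else model.pc_basis.shape[1])

    run_stage("harmonize", _harmonize)

    masked = None
    opnmf_input = None

    def _prep():
        nonlocal masked, opnmf_input
        from .simulate import VertexFeatureSet

        fs = VertexFeatureSet(ct=harmonized["ct"], sa=harmonized["sa"],
                              gi=harmonized["gi"], geometry=features.geometry,
                              subject_order=list(features.subject_order))
        masked = apply_midline_mask(fs)
        resid = residualize_on_volume(masked.metrics, volume)
        opnmf_input = build_opnmf_input(resid, masked.subject_order,
                                        mask=features.geometry.midline_mask)
        record("prep", n_vertices_kept=masked.ct.shape[0],
               n_columns=opnmf_input.V.shape[1],
               shift_value=opnmf_input.shift_value)

    run_stage("prep", _prep)

    selected_k = config.k

    def _stability():
        nonlocal selected_k
        curve = split_half_stability(
            masked.metrics, volume, masked.subject_order, config.k_grid,
            n_splits=config.n_splits_stability, seed=seeds["stability"],
            max_iter=config.max_iter, tol=config.tol,
            check_every=config.check_every,
        )
        curve.to_frame().to_csv(out / "stability_curve.csv", index=False)
        sel, report = select_k(curve, config.stability_floor,
                               config.error_gain_floor)
        (out / "k_selection.json").write_text(json.dumps(report, indent=1))
        selected_k = sel if config.k is None else config.k
        record("stability", selected_k=sel, no_elbow=report["no_elbow"])

    run_stage("stability", _stability)

    fit = None

    def _factorize():
        nonlocal fit
        k = selected_k if selected_k is not None else min(config.k_grid)
        fit = fit_opnmf(opnmf_input.V, k, max_iter=config.max_iter,
                        tol=config.tol, check_every=config.check_every)
        np.savetxt(out / "W.tsv", fit.W, fmt="%.8g", delimiter="\t")
        np.savetxt(out / "H.tsv", fit.H, fmt="%.8g", delimiter="\t")
        labels = winner_take_all(fit.W)
        np.savetxt(out / "component_labels.txt", labels, fmt="%d")
        (out / "factorization.json").write_text(json.dumps({
            "k": k, "n_iter": fit.n_iter, "converged": fit.converged,
            "final_objective": fit.objective_trace[-1],
        }))
        record("factorize", k=k, n_iter=fit.n_iter, converged=fit.converged)

    run_stage("factorize", _factorize)

    pls_res = None
    brain = behavior = None

    def _pls():
        nonlocal pls_res, brain, behavior
        brain, behavior, dropped = build_design_matrices(
            cohort, fit.H, opnmf_input.column_labels
        )
        res = fit_bpls(brain.X, behavior.Y, brain.column_labels,
                       behavior.column_labels)
        res.perm_p = permutation_pvalues(brain.X, behavior.Y,
                                         n_perm=config.n_perm,
                                         seed=seeds["pls"])
        res = bootstrap_saliences(brain.X, behavior.Y, n_boot=config.n_boot,
                                  seed=seeds["pls"] + 1, result=res)
        res.splithalf_p_left, res.splithalf_p_right = \
            split_half_singular_stability(
                brain.X, behavior.Y, n_splits=config.n_splits_pls,
                n_perm=config.n_perm_splithalf, seed=seeds["pls"] + 2,
            )
        lv, sal, scores = results_tables(res)
        lv.to_csv(out / "lv_summary.csv", index=False)
        sal.to_csv(out / "saliences.csv", index=False)
        scores.insert(0, "subject_id", brain.subject_ids)
        scores.to_csv(out / "scores.csv", index=False)
        pls_res = res
        record("pls", n_lv=res.n_lv, n_dropped=len(dropped),
               varexp_lv1=float(res.varexp[0]))

    run_stage("pls", _pls)

    def _associate():
        sub = cohort[cohort["subject_id"].isin(brain.subject_ids)]
        sub = sub.set_index("subject_id").loc[brain.subject_ids].reset_index()
        table = association_table(sub, pls_res.x_scores, pls_res.y_scores)
        table.to_csv(out / "associations.csv", index=False)
        record("associate", n_rows=len(table))

    run_stage("associate", _associate)

    manifest["total_seconds"] = round(time.time() - t0, 3)
    cfg_json = json.dumps(manifest["config"], sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    # timings differ between runs; keep them out of the reproducibility bundle
    stable_manifest = {k: v for k, v in manifest.items() if k != "total_seconds"}
    for st in stable_manifest["stages"].values():
        st.pop("seconds", None)
    (out / "manifest.json").write_text(json.dumps(stable_manifest, indent=1,
                                                  sort_keys=True))
    return {
        "cohort": cohort, "features": features, "harmonized": harmonized,
        "opnmf_input": opnmf_input, "selected_k": selected_k, "fit": fit,
        "pls": pls_res, "manifest": manifest, "outdir": out,
    }
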