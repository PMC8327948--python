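"""Per-pair and cross-pair orchestration of the full analysis.

``run_pair`` executes the standard stage order on one wild/domestic
dataset: superimposition, symmetric-component extraction, allometry
(Procrustes ANOVA, centroid-size t-test, allometric-vector comparison),
then — on the uncorrected and/or allometry-corrected branch — the
covariance-ratio modularity test, whole-cranium and per-form two-block
PLS, per-module eigenvalue dispersion, per-module disparity contrasts,
and PCA with the PC1/PLS1 alignment correlation.

``run_study`` aggregates several pair reports: average CR, the
dispersion contrast t-tests, the pairwise PLS effect-size comparison
(optionally excluding pairs flagged as having a reduced landmark set),
and the disparity~integration regressions.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry as allo
from . import covariation as cov
from . import disparity as disp
from . import downstream_stats as ds
from .gpa_symmetry import ShapeArrays, gpa, subset_module, symmetric_component
from .io_landmarks import (
    LandmarkDataset,
    ModuleMap,
    SymmetryPairing,
    read_landmarks,
    read_module_map,
    read_symmetry_pairing,
)
from .synthetic_data import SyntheticParams, simulate_dataset

BRANCHES = ("uncorrected", "corrected")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of a single-pair run.

    Exactly one input source: either the three file paths or a synthetic
    parameter set.  ``n_perm`` must be at least 99 so reported p-values
    have at least two significant digits of resolution.
    """

    landmarks_path: str | None = None
    module_map_path: str | None = None
    pairing_path: str | None = None
    dialect: str = "csv-wide"
    synthetic: SyntheticParams | None = None
    branch: str = "both"  # uncorrected | corrected | both
    n_perm: int = 1000
    seed: int = 0
    symmetry_axis: int = 1
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 1000
    reduced_landmarks: bool = False  # excluded from effect-size comparisons
    output_dir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.landmarks_path is not None
        if has_files == (self.synthetic is not None):
            raise PipelineError(
                "exactly one input source required: file paths or a synthetic preset"
            )
        if has_files and (self.module_map_path is None or self.pairing_path is None):
            raise PipelineError("module map and symmetry pairing paths required")
        if self.n_perm < 99:
            raise PipelineError("n_perm must be >= 99 for reported p-values")
        if self.branch not in ("uncorrected", "corrected", "both"):
            raise PipelineError(f"unknown branch '{self.branch}'")

    def branches(self) -> tuple[str, ...]:
        return BRANCHES if self.branch == "both" else (self.branch,)


def _load_inputs(
    config: PipelineConfig,
) -> tuple[LandmarkDataset, ModuleMap, SymmetryPairing]:
    if config.synthetic is not None:
        dataset, module_map, pairing, _ = simulate_dataset(config.synthetic)
        return dataset, module_map, pairing
    dataset = read_landmarks(config.landmarks_path, config.dialect)
    module_map = read_module_map(config.module_map_path, dataset)
    pairing = read_symmetry_pairing(config.pairing_path, dataset)
    return dataset, module_map, pairing


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def _branch_report(
    shapes: ShapeArrays,
    module_map: ModuleMap,
    labels: np.ndarray,
    n_perm: int,
    seeds: list[int],
) -> dict:
    """All covariation / disparity / ordination statistics for one branch."""
    mod = cov.modularity_test(shapes, module_map, n_perm=n_perm, seed=seeds[0])
    pls = cov.two_block_pls(shapes, module_map, n_perm=n_perm, seed=seeds[1], label="pair")
    ordination = ds.pca(shapes)
    r_nc, p_nc = ds.pc1_pls1_correlation(ordination, pls, block="NC")
    r_md, p_md = ds.pc1_pls1_correlation(ordination, pls, block="MD")

    dispersion = {}
    per_form_pls = {}
    for gi, g in enumerate(("wild", "domestic")):
        sel = np.flatnonzero(labels == g)
        sub = ShapeArrays(
            aligned=shapes.aligned[sel],
            centroid_size=shapes.centroid_size[sel],
            consensus=shapes.aligned[sel].mean(axis=0),
            symmetric=shapes.symmetric,
            group=[g] * len(sel),
            pair_id=shapes.pair_id,
        )
        dispersion[g] = {
            which: cov.eigenvalue_dispersion(sub, module_map, which).rel_eig_sd
            for which in ("NC", "MD")
        }
        per_form_pls[g] = cov.two_block_pls(
            sub, module_map, n_perm=n_perm, seed=seeds[2 + gi], label=f"form_{g}"
        )

    module_disp = disp.module_disparity(
        shapes, module_map, labels, n_perm=n_perm, seed=seeds[4]
    )
    whole_disp = disp.disparity_test(shapes, labels, n_perm=n_perm, seed=seeds[5])

    return {
        "modularity": {
            "CR": mod.cr_observed,
            "p": mod.p_value,
            "z": mod.effect_size_z,
        },
        "pls": {
            "r_pls": pls.r_pls,
            "p": pls.p_value,
            "z": pls.effect_size_z,
        },
        "_pls_result": pls,
        "per_form_pls": {
            g: {"r_pls": r.r_pls, "p": r.p_value, "z": r.effect_size_z}
            for g, r in per_form_pls.items()
        },
        "dispersion": dispersion,
        "disparity": {
            "whole": {
                "proc_var": whole_disp.proc_var,
                "p": whole_disp.p_values[("domestic", "wild")],
            },
            **{
                which: {
                    "proc_var": r.proc_var,
                    "proc_var_per_landmark": r.proc_var_per_landmark,
                    "p": r.p_values[("domestic", "wild")],
                }
                for which, r in module_disp.items()
            },
        },
        "pca": {
            "pc1_fraction": float(ordination.variance_fraction[0]),
            "n_axes_95": ordination.n_retained,
            "pc1_pls1_r_NC": r_nc,
            "pc1_pls1_p_NC": p_nc,
            "pc1_pls1_r_MD": r_md,
            "pc1_pls1_p_MD": p_md,
        },
    }


def run_pair(config: PipelineConfig) -> dict:
    """Run the full analysis on one wild/domestic pair.

    Returns a report dict (JSON-serializable except for the private
    ``_pls_result`` entries consumed by ``run_study``) and, if
    ``config.output_dir`` is set, writes the JSON summary and CSV tables
    there.
    """
    t0 = time.time()
    dataset, module_map, pairing = _load_inputs(config)
    labels = np.asarray(dataset.group)
    seeds = _stage_seeds(config.seed, 16)

    fit = gpa(dataset, tol=config.gpa_tol, max_iter=config.gpa_max_iter)
    sym, _asym = symmetric_component(
        fit, pairing, axis=config.symmetry_axis,
        tol=config.gpa_tol, max_iter=config.gpa_max_iter,
    )

    anova = allo.procrustes_anova(sym, n_perm=config.n_perm, seed=seeds[0])
    angle, angle_p = allo.compare_allometric_vectors(
        sym, labels, n_perm=config.n_perm, seed=seeds[1]
    )
    t_stat, t_df, t_p = allo.centroid_size_ttest(sym, labels)

    report: dict = {
        "pair_id": dataset.pair_id,
        "n_specimens": dataset.n_specimens,
        "n_landmarks": dataset.n_landmarks,
        "n_wild": int(np.sum(labels == "wild")),
        "n_domestic": int(np.sum(labels == "domestic")),
        "reduced_landmarks": config.reduced_landmarks,
        "n_perm": config.n_perm,
        "seed": config.seed,
        "allometry": {
            "r_squared": anova.r_squared,
            "f": anova.f_statistic,
            "z": anova.effect_size_z,
            "p": anova.p_value,
            "angle_wild_domestic_deg": angle,
            "angle_p": angle_p,
            "size_ttest": {"t": t_stat, "df": t_df, "p": t_p},
        },
        "branches": {},
    }

    branch_inputs = {}
    if "uncorrected" in config.branches():
        branch_inputs["uncorrected"] = sym
    if "corrected" in config.branches():
        branch_inputs["corrected"] = allo.allometry_residuals(anova)

    for bi, (name, shapes) in enumerate(branch_inputs.items()):
        report["branches"][name] = _branch_report(
            shapes, module_map, labels, config.n_perm, seeds[2 + 6 * bi : 8 + 6 * bi]
        )

    report["elapsed_s"] = round(time.time() - t0, 3)
    if config.output_dir is not None:
        _write_pair_outputs(report, Path(config.output_dir))
    return report


def strip_private(report: dict) -> dict:
    """Deep-copy a report without the private (non-serializable) entries."""
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items() if not str(k).startswith("_")}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return clean(report)


def _write_pair_outputs(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{report['pair_id']}_summary.json", "w") as fh:
        json.dump(strip_private(report), fh, indent=2)
    rows = []
    for branch, b in report["branches"].items():
        rows.append(
            {
                "pair": report["pair_id"],
                "branch": branch,
                "CR": b["modularity"]["CR"],
                "CR_p": b["modularity"]["p"],
                "r_pls": b["pls"]["r_pls"],
                "pls_p": b["pls"]["p"],
                "pls_z": b["pls"]["z"],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / f"{report['pair_id']}_covariation.csv", index=False)


def run_study(reports: list[dict], exclude_reduced: bool = True) -> dict:
    """Aggregate several pair reports into the cross-pair summary."""
    if len(reports) < 2:
        raise PipelineError("need at least 2 pair reports")
    branch_sets = [tuple(sorted(r["branches"])) for r in reports]
    if len(set(branch_sets)) != 1:
        raise PipelineError("inconsistent branch selection across pairs")
    branches = branch_sets[0]

    summary: dict = {"n_pairs": len(reports), "branches": {}}
    for branch in branches:
        bs = [r["branches"][branch] for r in reports]
        pair_ids = [r["pair_id"] for r in reports]

        disp_rows = []
        for pid, b in zip(pair_ids, bs):
            for form in ("wild", "domestic"):
                for module in ("NC", "MD"):
                    disp_rows.append(
                        {
                            "pair": pid,
                            "form": form,
                            "module": module,
                            "value": b["dispersion"][form][module],
                        }
                    )
        disp_df = pd.DataFrame(disp_rows)
        ttests = ds.dispersion_ttests(disp_df)

        keep = [
            (pid, b, r)
            for pid, b, r in zip(pair_ids, bs, reports)
            if not (exclude_reduced and r.get("reduced_landmarks"))
        ]
        effect_cmp = None
        if len(keep) >= 2 and all("_pls_result" in b for _, b, _ in keep):
            pls_results = [b["_pls_result"] for _, b, _ in keep]
            z_diff, p_mat = cov.compare_pls_effects(pls_results)
            effect_cmp = {
                "pairs": [pid for pid, _, _ in keep],
                "z_diff": z_diff.tolist(),
                "p": p_mat.tolist(),
            }

        # disparity~integration regressions over pair x form x module points
        obs = []
        for pid, b, r in zip(pair_ids, bs, reports):
            for form in ("wild", "domestic"):
                for module in ("NC", "MD"):
                    obs.append(
                        {
                            "pair": pid,
                            "form": form,
                            "module": module,
                            "disparity": b["disparity"][module][
                                "proc_var_per_landmark"
                            ][form],
                            "within_int": b["dispersion"][form][module],
                            "between_z": b["per_form_pls"][form]["z"],
                        }
                    )
        obs_df = pd.DataFrame(obs)
        reg_within = ds.disparity_integration_regression(
            obs_df["disparity"], obs_df["within_int"], obs_df["form"]
        )
        reg_between = ds.disparity_integration_regression(
            obs_df["disparity"], obs_df["between_z"], obs_df["form"]
        )

        summary["branches"][branch] = {
            "average_CR": float(np.mean([b["modularity"]["CR"] for b in bs])),
            "average_dispersion": {
                module: float(disp_df.loc[disp_df["module"] == module, "value"].mean())
                for module in ("NC", "MD")
            },
            "dispersion_ttests": ttests.to_dict(orient="records"),
            "effect_size_comparison": effect_cmp,
            "regression_within_integration": reg_within,
            "regression_between_integration": reg_between,
        }
    return summary
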