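"""End-to-end run: simulate -> preprocess -> DM screen -> clocks -> GLAD -> comparison.

A single master seed drives per-stage substreams, so a rerun with the
same configuration is byte-identical for every data output. The run
directory collects every stage's inputs and outputs as plain text
(CSV/TSV/JSON); plots are optional and never feed any statistic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .clock import clock_features, predict_age, train_clock
from .cohort import (
    CohortDesign,
    SimulationParams,
    generate_cohort,
    simulate_methylome,
    spike_contamination,
    truth_to_csv,
)
from .compare import compare_models
from .dm import three_level_screen
from .glad import compare_glad, compute_glad
from .preprocess import aggregate_regions, beta_to_m, purity_screen, qc_filter

__all__ = ["default_config", "load_config", "run_full_analysis"]


def default_config() -> dict:
    return {
        "seed": 0,
        "design": {"n_per_cell": 12},
        "params": {},
        "contamination": {"sample_ids": [], "fraction": 0.0},
        "preprocess": {"eps": 1e-6, "purity_threshold": 0.5, "max_missing_fraction": 0.1,
                       "exclude_impure": True},
        "dm": {"alpha": 0.05, "within": "age_category", "compare": "bmi_category"},
        "clock": {"alpha": 0.5, "k_folds": 10, "feature_scale": "beta", "lam": None},
        "plots": False,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _design_from(cfg: dict) -> CohortDesign:
    kwargs = dict(cfg.get("design") or {})
    for key in ("age_categories", "bmi_subcategories"):
        if key in kwargs:
            kwargs[key] = tuple(tuple(item) for item in kwargs[key])
    return CohortDesign(**kwargs)


def run_full_analysis(config: dict | str | Path, out_dir) -> dict:
    """Execute the whole analysis and write every artifact to ``out_dir``.

    Returns a results dict mirroring report.json. Any stage failure
    raises with a stage-tagged message.
    """
    cfg = load_config(config) if not isinstance(config, dict) else _merge_defaults(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(int(cfg["seed"])).spawn(4)]
    stage = "configuration"
    try:
        stage = "simulate"
        design = _design_from(cfg)
        params = SimulationParams(**(cfg.get("params") or {}))
        cohort = generate_cohort(design, seed=seeds[0])
        beta, region_map, truth = simulate_methylome(cohort, params, seed=seeds[1])
        contam = cfg.get("contamination") or {}
        contam_ids = list(contam.get("sample_ids") or [])
        if contam_ids and contam.get("fraction", 0.0) > 0:
            beta = spike_contamination(beta, contam_ids, float(contam["fraction"]), truth)
        cohort.to_csv(out / "cohort.csv", index=False)
        io.write_beta_tsv(beta, out / "beta.tsv")
        io.write_region_map(region_map, out / "regions.bed")
        truth_to_csv(truth, out / "truth_cpg_effects.csv", out / "truth_samples.csv")

        stage = "preprocess"
        pp = cfg["preprocess"]
        beta_qc, qc_report = qc_filter(beta, pp["max_missing_fraction"])
        purity = purity_screen(beta_qc, region_map, threshold=pp["purity_threshold"])
        purity.to_csv(out / "purity.csv", index=False)
        impure = purity.loc[purity["verdict"] == "fail", "sample"].tolist()
        analysis_samples = [s for s in beta_qc.columns if not (pp["exclude_impure"] and s in impure)]
        beta_a = beta_qc[analysis_samples]
        pheno = cohort[cohort["id"].isin(analysis_samples)].reset_index(drop=True)
        mvals = beta_to_m(beta_a, eps=pp["eps"])
        io.write_beta_tsv(mvals, out / "mvalues.tsv")

        stage = "differential_methylation"
        dmcfg = cfg["dm"]
        dm_results, dm_summary = three_level_screen(
            mvals, region_map, pheno, within=dmcfg["within"], compare=dmcfg["compare"], alpha=dmcfg["alpha"]
        )
        dm_results.to_csv(out / "dm_results.csv", index=False)
        dm_summary.to_csv(out / "dm_summary.csv", index=False)

        stage = "clock_training"
        ccfg = cfg["clock"]
        scale_matrix = beta_a if ccfg["feature_scale"] == "beta" else mvals
        region_matrix = aggregate_regions(scale_matrix, region_map)
        feats_no = clock_features(region_matrix, truth.clock_region_ids, cohort=pheno, include_bmi=False)
        feats_bmi = clock_features(region_matrix, truth.clock_region_ids, cohort=pheno, include_bmi=True)
        ages = pheno.set_index("id")["age"].reindex(feats_no.index).to_numpy()
        common = dict(alpha=ccfg["alpha"], k_folds=ccfg["k_folds"], lam=ccfg.get("lam"), seed=seeds[2])
        model_no = train_clock(feats_no, ages, include_bmi=False, **common)
        model_bmi = train_clock(feats_bmi, ages, include_bmi=True, **common)
        model_no.to_json(out / "model_without_bmi.json")
        model_bmi.to_json(out / "model_with_bmi.json")

        stage = "prediction"
        pred_no = predict_age(model_no, feats_no, ages=ages)
        pred_bmi = predict_age(model_bmi, feats_bmi, ages=ages)
        pred_no.to_csv(out / "predictions_without_bmi.csv", index=False)
        pred_bmi.to_csv(out / "predictions_with_bmi.csv", index=False)

        stage = "glad"
        glad = compute_glad(pred_no)
        summary, tests, long = compare_glad(glad, pheno)
        long.to_csv(out / "glad.csv", index=False)
        summary.to_csv(out / "glad_summary.csv", index=False)
        tests.to_csv(out / "glad_tests.csv", index=False)

        stage = "model_comparison"
        report = compare_models(pred_no, pred_bmi, config={"seed": int(cfg["seed"])})
        report.to_json(out / "comparison_report.json")

        stage = "report"
        results = {
            "n_samples": int(len(cohort)),
            "n_analysis_samples": int(len(analysis_samples)),
            "clock": {
                "n_features_without_bmi": model_no.n_features,
                "n_features_with_bmi": model_bmi.n_features,
                "lambda_without_bmi": model_no.lam,
                "lambda_with_bmi": model_bmi.lam,
            },
            "marker_region_cpgs": len(region_map.probes(region_map.marker_region)),
            "impure_samples": impure,
            "qc": {k: v for k, v in qc_report.items() if k != "dropped_probes"},
            "dm_significant": {
                level: int(dm_summary.loc[dm_summary["level"] == level, "n_significant"].sum())
                for level in ("point", "regional", "global")
            },
            "glad_tests": tests.to_dict(orient="records"),
            "glad_summary": summary.to_dict(orient="records"),
            "model_comparison": report.to_dict(),
            "config": _jsonable(cfg),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")

        if cfg.get("plots"):
            stage = "plots"
            _write_plots(out, pred_no, pred_bmi, long)
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _merge_defaults(config: dict) -> dict:
    cfg = default_config()
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_plots(out: Path, pred_no: pd.DataFrame, pred_bmi: pd.DataFrame, glad_long: pd.DataFrame):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharex=True, sharey=True)
    for ax, pred, title in zip(axes, (pred_no, pred_bmi), ("without BMI", "with BMI")):
        a, p = pred["actual_age"], pred["predicted_age"]
        ax.scatter(a, p, s=18, alpha=0.7)
        lims = [min(a.min(), p.min()), max(a.max(), p.max())]
        ax.plot(lims, lims, "k--", lw=1, label="identity")
        slope, intercept = np.polyfit(a, p, 1)
        xs = np.linspace(*lims, 50)
        ax.plot(xs, intercept + slope * xs, "r-", lw=1, label="fit")
        ax.set_xlabel("actual age (y)")
        ax.set_title(title)
        ax.legend(frameon=False)
    axes[0].set_ylabel("predicted age (y)")
    fig.tight_layout()
    fig.savefig(out / "age_prediction_scatter.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    cats = list(dict.fromkeys(glad_long["age_category"]))
    positions, data, labels = [], [], []
    pos = 0
    for cat in cats:
        for bmi in ("normal", "high"):
            vals = glad_long.loc[
                (glad_long["age_category"] == cat) & (glad_long["bmi_category"] == bmi), "glad"
            ]
            data.append(vals)
            positions.append(pos)
            labels.append(f"{cat}\n{bmi}")
            pos += 1
        pos += 0.6
    ax.boxplot(data, positions=positions, widths=0.7)
    ax.set_xticks(positions, labels, fontsize=7)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("GLAD")
    fig.tight_layout()
    fig.savefig(out / "glad_boxplot.png", dpi=120)
    plt.close(fig)
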