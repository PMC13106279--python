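"""Pipeline orchestration: preprocess -> segment -> extract -> analyze ->
classify, with reproducible run manifests.

``run_extract`` turns preprocessed recordings into the 60-column feature
table; ``run_analysis`` performs the cohort-level statistics (cleaning,
imputation, group effects, factor composites, reliability, integrated
outcome, mediation, and pre/post confounder-adjustment classification)
and writes a report bundle of TSV/JSON artifacts.
"""

from __future__ import annotations

import json
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import loocv_evaluate
from .cohort_stats import (
    cart_impute,
    clean_outliers,
    composite_alphas,
    fit_factor_model,
    group_effect,
    integrated_outcome,
    mediation_paths,
    parallel_analysis,
)
from .config import PipelineConfig
from .network import FEATURE_NAMES, assemble_feature_vector
from .segmentation import detect_bursts
from .signal_io import EmgRecording, MvcReference, attenuate_crosstalk, normalize_to_mvc, preprocess_filter

__all__ = ["preprocess_recording", "run_extract", "run_analysis", "run_manifest"]


def run_manifest(config: PipelineConfig, seed: int, extra: dict | None = None) -> dict:
    import scipy
    import sklearn
    import statsmodels

    m = {
        "schema_version": config.schema_version,
        "config_hash": config.config_hash(),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    if extra:
        m.update(extra)
    return m


def preprocess_recording(
    rec: EmgRecording,
    mvc_ref: MvcReference | None = None,
    config: PipelineConfig | None = None,
) -> EmgRecording:
    """Filter -> crosstalk attenuation -> MVC normalization."""
    config = config or PipelineConfig()
    rec = preprocess_filter(rec, config.filter)
    if config.crosstalk.enabled and rec.n_channels > 1:
        rec = attenuate_crosstalk(rec, seed=config.crosstalk.seed)
    if mvc_ref is not None and rec.units == "mV_gained":
        rec = normalize_to_mvc(rec, mvc_ref)
    rec.validate()
    return rec


def run_extract(
    recordings,
    config: PipelineConfig | None = None,
    mvc_refs: dict | None = None,
    preprocess: bool = True,
    out_path=None,
) -> tuple[pd.DataFrame, dict]:
    """Extract the 60-feature vector for each recording.

    ``recordings`` is an iterable of EmgRecording (or (recording, meta)
    tuples whose meta is carried into the output rows). Per-recording
    failures are recorded in the manifest and skipped; the feature table
    gets one row per successful recording."""
    config = config or PipelineConfig()
    rows = []
    failures = []
    for item in recordings:
        rec, meta = item if isinstance(item, tuple) else (item, {})
        meta = dict(meta or {})
        try:
            ref = (mvc_refs or {}).get(rec.subject_id)
            if preprocess:
                rec = preprocess_recording(rec, ref, config)
            bursts = detect_bursts(rec, config.burst)
            feats = assemble_feature_vector(rec, bursts, config, mvc_ref=ref)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "task": rec.task,
                    "group": rec.group,
                    **meta,
                    **feats,
                }
            )
        except Exception as exc:  # per-recording failure: log and continue
            failures.append({"subject_id": rec.subject_id, "task": rec.task, "error": str(exc)})
    table = pd.DataFrame(rows)
    manifest = run_manifest(config, config.seed, {"n_recordings": len(rows), "failures": failures})
    if out_path is not None:
        out_path = Path(out_path)
        table.to_csv(out_path, sep="\t", index=False, float_format="%.10g")
        out_path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))
    return table, manifest


def _write_roc_plot(report, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (c1, c2), r in report.roc.items():
        ax.plot(r["fpr"], r["tpr"], label=f"{c1} vs {c2} (AUC={r['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_analysis(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    out_dir=None,
    outcome_weights: tuple = (1.0, 1.0, 1.0),
    plots: bool = False,
) -> dict:
    """Full cohort analysis of a feature table with metadata columns.

    Required columns: the 60 features, ``subject_id``, ``group``,
    ``age``, ``sex``, ``MoCA``, ``Bulb_ALSFRS``, ``Intell``, ``SR``,
    ``stiffness``. Returns a report bundle; writes TSV/JSON artifacts to
    ``out_dir`` when given."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    required = list(FEATURE_NAMES) + [
        "subject_id", "group", "age", "sex", "MoCA",
        "Bulb_ALSFRS", "Intell", "SR", "stiffness",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    table = table.reset_index(drop=True)

    # 1. cleaning + imputation
    cleaned, flags = clean_outliers(table, FEATURE_NAMES, config.stats.iqr_multiplier)
    completed = cart_impute(cleaned, FEATURE_NAMES, seed=seed, config=config.stats)

    # 2. per-feature group effects (ALS vs HC)
    is_als = (completed["group"] != "HC").to_numpy()
    subj = completed["subject_id"].to_numpy()
    effects = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for feat in FEATURE_NAMES:
            ge = group_effect(completed[feat].to_numpy(), is_als, subj)
            effects.append(
                {
                    "feature": feat,
                    "estimate": ge.estimate,
                    "cohens_d": ge.cohens_d,
                    "ci_low": ge.ci[0],
                    "ci_high": ge.ci[1],
                    "method": ge.method,
                }
            )
    effects_df = pd.DataFrame(effects)

    # 3. factor composites
    X = completed[FEATURE_NAMES]
    k = parallel_analysis(
        X.to_numpy(), n_sims=config.stats.pa_n_sims, seed=seed,
        percentile=config.stats.pa_percentile,
    )
    k = max(k, 1)
    model = fit_factor_model(X, k, loading_cutoff=config.stats.loading_cutoff)
    alphas = composite_alphas(completed, model)

    # 4. integrated outcome + mediation
    outcome = integrated_outcome(completed, weights=outcome_weights)
    med = mediation_paths(
        model.scores,
        completed["stiffness"],
        outcome,
        completed["subject_id"],
        n_boot=config.stats.n_boot,
        seed=seed,
    )
    med_df = pd.DataFrame(
        {
            "composite": m.composite,
            "direct": m.direct,
            "a_path": m.a_path,
            "b_path": m.b_path,
            "indirect": m.indirect,
            "ci_low": m.indirect_ci[0],
            "ci_high": m.indirect_ci[1],
        }
        for m in med
    )

    # 5. classification pre/post confounder adjustment
    covs = pd.DataFrame(
        {
            "age": completed["age"],
            "sex": completed["sex"],
            "cognitive_status": (completed["MoCA"] < config.stats.moca_cutoff).astype(int),
        }
    )
    y = completed["group"].to_numpy()
    scores_X = model.scores.to_numpy()
    groups = subj if config.classifier.loocv_level == "subject" else None
    reports = {}
    for algo in ("mda", "svm_rbf"):
        reports[f"{algo}_pre"] = loocv_evaluate(
            scores_X, y, algo=algo, config=config.classifier, seed=seed, groups=groups
        )
        reports[f"{algo}_post"] = loocv_evaluate(
            scores_X, y, algo=algo, config=config.classifier, seed=seed,
            covariates=covs, groups=groups,
        )

    bundle = {
        "n_recordings": len(completed),
        "n_outliers_flagged": int(flags.to_numpy().sum()),
        "effects": effects_df,
        "n_factors": int(k),
        "factor_model": model,
        "variance_explained": model.variance_explained,
        "alphas": alphas,
        "outcome": outcome,
        "mediation": med_df,
        "classification": reports,
        "manifest": run_manifest(config, seed),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        effects_df.to_csv(out / "group_effects.tsv", sep="\t", index=False, float_format="%.8g")
        model.loadings.to_csv(out / "factor_loadings.tsv", sep="\t", float_format="%.8g")
        model.scores.to_csv(out / "factor_scores.tsv", sep="\t", float_format="%.8g")
        med_df.to_csv(out / "mediation.tsv", sep="\t", index=False, float_format="%.8g")
        summary = {
            "n_recordings": bundle["n_recordings"],
            "n_outliers_flagged": bundle["n_outliers_flagged"],
            "n_factors": bundle["n_factors"],
            "variance_explained": bundle["variance_explained"],
            "alphas": {k2: float(v) for k2, v in alphas.items()},
            "component_map": model.component_map,
            "classification": {name: r.to_dict() for name, r in reports.items()},
            "manifest": bundle["manifest"],
        }
        (out / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        for name, r in reports.items():
            pd.DataFrame(
                r.confusion, index=r.classes, columns=r.classes
            ).to_csv(out / f"confusion_{name}.tsv", sep="\t")
            roc_rows = []
            for (c1, c2), rr in r.roc.items():
                for fp, tp in zip(rr["fpr"], rr["tpr"]):
                    roc_rows.append({"pair": f"{c1} vs {c2}", "fpr": fp, "tpr": tp})
            pd.DataFrame(roc_rows).to_csv(
                out / f"roc_{name}.tsv", sep="\t", index=False, float_format="%.8g"
            )
        if plots:
            _write_roc_plot(reports["svm_rbf_pre"], out / "roc_svm_pre.png")
    return bundle
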