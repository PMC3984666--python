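"""End-to-end pipeline: clean -> normalize -> batch-correct -> average ->
univariate -> multivariate (full + refined) -> external validation -> ROC.

Each stage failure is re-raised with the stage name for context.  All
outputs are deterministic for a fixed seed, re-readable by this package's
own readers, and written under one results directory:

* ``cleaning_report.json``   per-rule removal counts and reasons
* ``precision.json``         per-study median QC RSD
* ``univariate.tsv``         per-feature p, q, fold change, direction
* ``counts.json``            significance counts at the reporting thresholds
* ``model_summaries.json``   OPLS-DA figures of merit (full / refined /
  external), components string "predictive + orthogonal + 0"
* ``pca_scores.tsv``, ``opls_scores.tsv``, ``roc_<year>.tsv``
* ``run_log.txt``            package/library versions, seed and parameters
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import FeatureTable, ValidationError
from .io import PipelineConfig, read_feature_table, read_metadata, write_json
from .multivariate import (OPLSDA, PCAModel, UnitVarianceScaler, external_validate,
                           fit_cv_anova, impute_missing_by_year, refine_by_year,
                           select_components)
from .preprocess import (average_replicates, batch_correct, clean, compute_precision,
                         median_normalize)
from .roc import roc_result
from .univariate import adaptive_fdr, anova_matrix, count_significant, fold_change_matrix

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ValidationError, ValueError) as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err
        return wrapper
    return deco


def _model_summary(name, classes, report, suggested, r2y=None):
    if not suggested:
        return {"model": name, "classes": classes, "components": "0 + 0 + 0",
                "R2Y(cum)": None, "Q2(cum)": None, "p(CV-ANOVA)": None,
                "correct_classification_rate": None}
    return {
        "model": name, "classes": classes,
        "components": report.components_string,
        "R2Y(cum)": r2y,
        "Q2(cum)": report.q2,
        "p(CV-ANOVA)": report.p,
        "correct_classification_rate": f"{report.n_correct}/{report.n_total}",
    }


def run_pipeline(config: PipelineConfig, table: FeatureTable | None = None,
                 meta: pd.DataFrame | None = None) -> dict:
    """Run the whole analysis; returns a dict of in-memory results.

    ``table``/``meta`` may be passed directly (e.g. fresh from the
    simulator); otherwise they are read from the paths in ``config``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if table is None:
        if config.feature_table is None or config.metadata is None:
            raise PipelineError("stage 'load' failed: no feature table or metadata given")
        table = read_feature_table(config.feature_table)
        meta = read_metadata(config.metadata, table)

    results: dict = {}

    # ---- cleaning ---------------------------------------------------------
    table, reports = _stage("clean")(clean)(
        table, meta, rt_window_s=config.rt_window_s,
        mz_window_amu=config.mz_window_amu,
        intensity_fraction=config.intensity_fraction,
        blank_ratio=config.blank_ratio, rt_cutoff_s=config.rt_cutoff_s)
    write_json([r.to_dict() for r in reports], out_dir / "cleaning_report.json")
    results["cleaning_reports"] = reports

    # ---- normalization / batch correction / averaging ---------------------
    table = _stage("normalize")(median_normalize)(table)
    table = _stage("batch_correct")(batch_correct)(table, meta)
    rsd, median_rsd = _stage("precision")(compute_precision)(table, meta)
    write_json({"median_rsd_percent": median_rsd}, out_dir / "precision.json")
    results["median_rsd_percent"] = median_rsd
    matrix, sample_meta = _stage("average")(average_replicates)(table, meta)
    matrix = impute_missing_by_year(matrix, sample_meta["year"])
    results["matrix"] = matrix
    results["sample_meta"] = sample_meta

    # ---- univariate -------------------------------------------------------
    in_c = (sample_meta["system"] == "C").to_numpy()
    pooled = np.where(in_c, "C", "O")
    years = sample_meta["year"].to_numpy()
    anova = _stage("univariate")(anova_matrix)(matrix, pooled, years)
    fdr_sys = adaptive_fdr(anova["p_a"].to_numpy())
    fdr_year = adaptive_fdr(anova["p_b"].to_numpy())
    fc = fold_change_matrix(matrix, in_c, years)
    uni = pd.DataFrame({
        "p_system": anova["p_a"], "p_year": anova["p_b"],
        "q_system": fdr_sys.qvalues, "q_year": fdr_year.qvalues,
        "fold_change": fc["magnitude"], "direction": fc["direction"],
    }, index=matrix.columns)
    uni.to_csv(out_dir / "univariate.tsv", sep="\t", index_label="feature_id",
               float_format="%.6g")
    counts = {
        "C_vs_O1/O2": count_significant(anova["p_a"], fdr_sys.qvalues, fdr_sys.m0_hat,
                                        p_thresholds=config.p_thresholds,
                                        q_thresholds=config.fdr_thresholds),
        "2007_vs_2008": count_significant(anova["p_b"], fdr_year.qvalues, fdr_year.m0_hat,
                                          p_thresholds=config.p_thresholds,
                                          q_thresholds=config.fdr_thresholds),
    }
    write_json(counts, out_dir / "counts.json")
    results["univariate"] = uni
    results["counts"] = counts

    if config.skip_multivariate:
        _write_log(config, out_dir)
        return results

    # ---- multivariate: full dataset ---------------------------------------
    y_sys = in_c.astype(float)  # C = 1, O1/O2 = 0
    yr_levels = pd.unique(years)
    y_year = (years == yr_levels[-1]).astype(float)
    scaler = UnitVarianceScaler()
    X = _stage("scale")(scaler.fit_transform)(matrix.to_numpy())
    pca = _stage("pca")(PCAModel(n_components=2).fit)(X)
    pd.DataFrame(pca.scores_, index=matrix.index, columns=["PC1", "PC2"]).to_csv(
        out_dir / "pca_scores.tsv", sep="\t", index_label="sample", float_format="%.6g")

    summaries = []

    def run_model(name, classes, Xm, y):
        n_ortho, rep = select_components(Xm, y, max_ortho=config.max_ortho,
                                         folds=config.cv_folds, delta_q2=config.delta_q2)
        r2y = None
        if n_ortho is not None:
            fit_cv_anova(rep, y)
            r2y = OPLSDA(n_ortho=n_ortho).fit(Xm, y).r2y_
        summaries.append(_model_summary(name, classes, rep, n_ortho is not None, r2y))
        return n_ortho, rep

    sel = _stage("model_full")(run_model)
    n_sys, rep_sys = sel("full: C vs O1/O2", ["C", "O1/O2"], X, y_sys)
    n_year, rep_year = sel("full: year", [str(yr_levels[0]), str(yr_levels[-1])], X, y_year)
    if n_sys is not None:
        model_sys = OPLSDA(n_ortho=n_sys).fit(X, y_sys)
        scores = pd.DataFrame({"t": model_sys.t_}, index=matrix.index)
        if model_sys.n_ortho_ > 0:
            scores["t_o1"] = model_sys.T_o_[:, 0]
        scores.to_csv(out_dir / "opls_scores.tsv", sep="\t", index_label="sample",
                      float_format="%.6g")

    # ---- refinement: remove year-dominated variables ----------------------
    kept, year_model, _ = _stage("refine")(refine_by_year)(
        X, years, max_ortho=config.max_ortho, folds=config.cv_folds,
        vip_threshold=config.vip_threshold)
    results["kept_variables"] = matrix.columns[kept]
    results["n_removed_by_vip"] = int(X.shape[1] - kept.size)
    Xr = X[:, kept]
    refined = _stage("model_refined")(run_model)
    refined("refined: C vs O1/O2", ["C", "O1/O2"], Xr, y_sys)
    refined("refined: year", [str(yr_levels[0]), str(yr_levels[-1])], Xr, y_year)

    # ---- external cross-year validation + ROC -----------------------------
    raw = matrix.to_numpy()[:, scaler.kept_][:, kept]
    roc_out = {}
    ext_rates = []
    for train_year in yr_levels:
        train = years == train_year
        test = ~train
        res = _stage("external_validate")(external_validate)(
            raw[train], y_sys[train], raw[test], y_sys[test],
            max_ortho=config.max_ortho, folds=min(config.cv_folds, int(train.sum())))
        test_year = [y for y in yr_levels if y != train_year][0]
        ext_rates.append(res["rate"])
        rr = _stage("roc")(roc_result)(res["y_pred"], y_sys[test].astype(bool))
        roc_out[str(test_year)] = {"auc": rr.auc, "u": rr.u, "p": rr.p,
                                   "n_pos": rr.n_pos, "n_neg": rr.n_neg}
        pd.DataFrame({"fpr": rr.fpr, "tpr": rr.tpr}).to_csv(
            out_dir / f"roc_{test_year}.tsv", sep="\t", index=False, float_format="%.6g")
        summaries.append({
            "model": f"external: train {train_year} -> predict {test_year}",
            "classes": ["C", "O1/O2"],
            "components": res["cv_report"].components_string if res["suggested"] else "1 + 0 + 0",
            "correct_classification_rate": f"{res['n_correct']}/{res['n_total']}",
        })
    summaries.append({"model": "external: mean", "classes": ["C", "O1/O2"],
                      "correct_classification_rate_percent": 100.0 * float(np.mean(ext_rates))})
    write_json(summaries, out_dir / "model_summaries.json")
    write_json(roc_out, out_dir / "roc_summary.json")
    results["model_summaries"] = summaries
    results["roc"] = roc_out
    results["external_rate_mean"] = float(np.mean(ext_rates))

    _write_log(config, out_dir)
    return results


def _write_log(config: PipelineConfig, out_dir: Path) -> None:
    from importlib.metadata import version

    import scipy

    libs = ", ".join(f"{m} {v}" for m, v in (
        ("numpy", np.__version__), ("scipy", scipy.__version__),
        ("pandas", pd.__version__), ("click", version("click")),
        ("pyyaml", version("pyyaml"))))
    lines = [f"agrimet {__version__}", libs, "parameters:"]
    paths = {"feature_table", "metadata", "out_dir"}
    for f in dataclasses.fields(config):
        if f.name not in paths:
            lines.append(f"  {f.name} = {getattr(config, f.name)!r}")
    (out_dir / "run_log.txt").write_text("\n".join(lines) + "\n")
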