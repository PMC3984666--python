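"""Delimited-text I/O for feature tables, injection metadata and config.

All tables are tab-delimited UTF-8 with '.' decimal separator; lines
starting with '#' in the header region are comments.  The feature-table
layout is::

    feature_id  mode  mz  rt_s  <injection_id_1>  <injection_id_2> ...

Missing intensities are empty cells, never 0.  Configuration is YAML; the
cleaning/model parameters default to the published protocol values
(0.5 s ringing window, +0.3 amu, 20% intensity, blank ratio 5, 60 s void
volume, sevenfold CV, VIP threshold 1.0).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable, META_COLUMNS, ValidationError, validate_metadata

__all__ = [
    "PipelineConfig", "read_feature_table", "write_feature_table",
    "read_metadata", "write_metadata", "load_config",
]

_FEATURE_COLS = ("feature_id", "mode", "mz", "rt_s")


@dataclass
class PipelineConfig:
    """Parameters of the end-to-end pipeline (defaults = protocol values)."""

    feature_table: str | None = None
    metadata: str | None = None
    out_dir: str = "results"
    rt_window_s: float = 0.5
    mz_window_amu: float = 0.3
    intensity_fraction: float = 0.2
    blank_ratio: float = 5.0
    rt_cutoff_s: float = 60.0
    fdr_thresholds: tuple = (0.05, 0.1)
    p_thresholds: tuple = (0.001, 0.05)
    cv_folds: int = 7
    vip_threshold: float = 1.0
    delta_q2: float = 0.01
    max_ortho: int = 10
    skip_multivariate: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.rt_window_s < 0 or self.mz_window_amu <= 0:
            raise ValidationError("filter windows must be positive")
        if not 0 < self.intensity_fraction <= 1:
            raise ValidationError("intensity_fraction must be in (0, 1]")
        if self.blank_ratio <= 0 or self.rt_cutoff_s < 0:
            raise ValidationError("blank_ratio must be > 0 and rt_cutoff_s >= 0")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("fdr_thresholds", "p_thresholds"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _fmt(x: float) -> str:
    if np.isnan(x):
        return ""
    return f"{x:.6g}"


def write_feature_table(table: FeatureTable, path, comments: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        cols = list(table.injection_ids)
        fh.write("\t".join(_FEATURE_COLS + tuple(cols)) + "\n")
        mz = table.features["mz"].to_numpy()
        rt = table.features["rt_s"].to_numpy()
        modes = table.features["mode"].to_numpy()
        vals = table.intensities.to_numpy()
        for i, fid in enumerate(table.feature_ids):
            row = [str(fid), modes[i], _fmt(mz[i]), _fmt(rt[i])]
            row.extend(_fmt(v) for v in vals[i])
            fh.write("\t".join(row) + "\n")


def read_feature_table(path) -> FeatureTable:
    """Parse a feature table with strict typing; empty cells become NaN."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str, "mode": str})
    missing = [c for c in _FEATURE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df.empty:
        import warnings

        warnings.warn(f"{path}: empty data section", stacklevel=2)
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        line = int(df.index[df["feature_id"] == dup][1]) + 2
        raise ValidationError(f"{path}: duplicate feature_id {dup!r} (line {line})")
    for col in ("mz", "rt_s"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValidationError(f"{path}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    features = df[list(_FEATURE_COLS)].set_index("feature_id")
    inj_cols = [c for c in df.columns if c not in _FEATURE_COLS]
    intensities = df[["feature_id"] + inj_cols].set_index("feature_id").astype(float)
    return FeatureTable(features, intensities)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="injection_id")


def read_metadata(path, table: FeatureTable | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="injection_id")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: metadata missing column(s) {missing}")
    for col in ("system",):
        df[col] = df[col].where(df[col].notna(), None)
    for col in ("year", "plot", "extraction_batch", "technical_replicate"):
        try:
            df[col] = df[col].astype("Int64")
        except (TypeError, ValueError):
            pass  # non-integer labels (e.g. string years) are allowed
    if "sampling_duplicate" in df.columns:
        df["sampling_duplicate"] = df["sampling_duplicate"].astype(bool)
    return validate_metadata(df, table)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default, allow_nan=True)
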