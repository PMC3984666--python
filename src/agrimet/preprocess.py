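"""Peak-list cleaning, normalization, batch correction and replicate averaging.

The cleaning rules operate on one aligned feature table per study and are
applied per ionization mode, in the order ringing -> blank -> void volume:

* ringing filter: removes low-intensity satellite peaks sitting within
  0.5 s and (0, +0.3) amu of a stronger peak at < 20% of its intensity;
* blank filter: removes features whose sample/blank median-intensity
  ratio is below 5;
* void-volume filter: removes features eluting before 60 s.

Normalization is sample-wise (each injection's median feature intensity is
brought to a common value), batch correction is variable-wise (extraction-QC
median ratio batch2/batch1 divides batch-2 intensities), and replicates are
averaged down to one row per biological sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CleaningReport, FeatureTable, MODES, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "remove_ringing", "remove_blank_features", "remove_void_volume",
    "clean", "median_normalize", "batch_correct", "average_replicates",
    "compute_precision", "reference_intensity",
]


def reference_intensity(table: FeatureTable, meta: pd.DataFrame | None = None) -> pd.Series:
    """Per-feature reference intensity: median over sample-role injections.

    Falls back to the median over all injections when no metadata is given
    (e.g. for a bare table fresh from the simulator).
    """
    if meta is not None:
        cols = meta.index[meta["role"] == "sample"].intersection(table.injection_ids)
        if len(cols):
            return table.intensities[cols].median(axis=1, skipna=True)
    return table.intensities.median(axis=1, skipna=True)


def remove_ringing(table: FeatureTable, meta: pd.DataFrame | None = None, *,
                   rt_window_s: float = 0.5, mz_window_amu: float = 0.3,
                   intensity_fraction: float = 0.2):
    """Remove ringing satellites: peaks within ``rt_window_s`` and
    (0, ``mz_window_amu``) above a stronger surviving peak at strictly less
    than ``intensity_fraction`` of its reference intensity.

    Features are visited in descending reference intensity so that a removed
    satellite can never anchor further removals; modes are independent.
    Returns ``(filtered_table, CleaningReport)``.
    """
    report = CleaningReport("ringing", before_per_mode=table.mode_counts())
    if table.n_features == 0:
        report.after_per_mode = dict(report.before_per_mode)
        return table, report
    ref = reference_intensity(table, meta)
    removed: dict[str, str] = {}
    for mode in MODES:
        in_mode = table.features.index[table.features["mode"] == mode]
        if len(in_mode) < 2:
            continue
        sub = table.features.loc[in_mode]
        order = ref.loc[in_mode].sort_values(ascending=False, kind="stable").index
        mz = sub["mz"]
        rt = sub["rt_s"]
        # survivors bucketed by m/z so each candidate checks only 2 buckets
        buckets: dict[int, list[str]] = {}
        for fid in order:
            m, r, v = mz[fid], rt[fid], ref[fid]
            b = int(m / mz_window_amu)
            hit = None
            for bb in (b - 1, b):  # anchor m/z lies below the satellite's
                for gid in buckets.get(bb, ()):
                    d = m - mz[gid]
                    if (0.0 < d < mz_window_amu and abs(r - rt[gid]) <= rt_window_s
                            and ref[gid] > v and v < intensity_fraction * ref[gid]):
                        hit = gid
                        break
                if hit:
                    break
            if hit:
                removed[fid] = f"ringing satellite of {hit}"
            else:
                buckets.setdefault(b, []).append(fid)
    out = table.drop(list(removed))
    report.removed = removed
    report.after_per_mode = out.mode_counts()
    report.check()
    return out, report


def remove_blank_features(table: FeatureTable, meta: pd.DataFrame, *,
                          min_ratio: float = 5.0):
    """Remove blank-borne features: sample/blank median ratio < ``min_ratio``.

    A blank median of 0 keeps the feature (the ratio is unbounded).  Raises
    if no extraction-blank injections are present; skip the filter
    explicitly in that case.
    """
    report = CleaningReport("blank", before_per_mode=table.mode_counts())
    blank_cols = meta.index[meta["role"] == "extraction_blank"].intersection(table.injection_ids)
    if len(blank_cols) == 0:
        raise ValidationError(
            "no extraction_blank injections present; skip the blank filter explicitly"
        )
    sample_cols = meta.index[meta["role"] == "sample"].intersection(table.injection_ids)
    removed: dict[str, str] = {}
    sm = table.intensities[sample_cols].median(axis=1, skipna=True)
    bm = table.intensities[blank_cols].median(axis=1, skipna=True)
    flag = (bm > 0) & (sm / bm < min_ratio)
    flag = flag.fillna(False)
    for fid in table.features.index[flag]:
        removed[fid] = f"sample/blank median ratio {sm[fid] / bm[fid]:.3g} < {min_ratio:g}"
    out = table.drop(list(removed))
    report.removed = removed
    report.after_per_mode = out.mode_counts()
    report.check()
    return out, report


def remove_void_volume(table: FeatureTable, rt_cutoff_s: float = 60.0):
    """Remove features eluting in the void volume (rt strictly below cutoff)."""
    if rt_cutoff_s < 0:
        raise ValidationError("rt cutoff must be >= 0")
    report = CleaningReport("void_volume", before_per_mode=table.mode_counts())
    flag = table.features["rt_s"] < rt_cutoff_s
    removed = {fid: f"rt {table.features.at[fid, 'rt_s']:.1f} s < {rt_cutoff_s:g} s"
               for fid in table.features.index[flag]}
    out = table.drop(list(removed))
    report.removed = removed
    report.after_per_mode = out.mode_counts()
    report.check()
    return out, report


def clean(table: FeatureTable, meta: pd.DataFrame, *, rt_window_s: float = 0.5,
          mz_window_amu: float = 0.3, intensity_fraction: float = 0.2,
          blank_ratio: float = 5.0, rt_cutoff_s: float = 60.0):
    """Apply the three cleaning rules in order ringing -> blank -> void volume."""
    table, r1 = remove_ringing(table, meta, rt_window_s=rt_window_s,
                               mz_window_amu=mz_window_amu,
                               intensity_fraction=intensity_fraction)
    table, r2 = remove_blank_features(table, meta, min_ratio=blank_ratio)
    table, r3 = remove_void_volume(table, rt_cutoff_s)
    return table, [r1, r2, r3]


def median_normalize(table: FeatureTable) -> FeatureTable:
    """Sample-wise normalization: scale each injection so its median feature
    intensity equals a common value.

    The common value is the grand median of the per-injection medians,
    computed per ionization mode (the two peak lists are normalized
    independently).  Relative intensities within an injection are unchanged.
    """
    out = table.intensities.copy()
    for mode in MODES:
        feat_rows = table.features["mode"] == mode
        if not feat_rows.any():
            continue
        block = out.loc[feat_rows]
        cols = block.columns[block.notna().any(axis=0)]
        if len(cols) == 0:
            continue
        medians = block[cols].median(axis=0, skipna=True)
        zero = medians.index[(medians <= 0) | medians.isna()]
        if len(zero):
            raise ValidationError(
                f"injection(s) without positive intensities: {list(zero[:5])}"
            )
        common = float(medians.median())
        out.loc[feat_rows, cols] = block[cols] * (common / medians)
    return FeatureTable(table.features.copy(), out)


def batch_correct(table: FeatureTable, meta: pd.DataFrame) -> FeatureTable:
    """Variable-wise batch correction using extraction-QC medians.

    For each feature, factor = median(QC, batch 2) / median(QC, batch 1);
    all batch-2 intensities of the feature are divided by the factor.
    Features with a zero batch-1 QC median are left unscaled and logged.
    """
    qc = meta[meta["role"] == "extraction_qc"]
    qc1 = qc.index[qc["extraction_batch"] == 1].intersection(table.injection_ids)
    qc2 = qc.index[qc["extraction_batch"] == 2].intersection(table.injection_ids)
    if len(qc1) == 0 or len(qc2) == 0:
        raise ValidationError("both batches need at least one extraction QC injection")
    m1 = table.intensities[qc1].median(axis=1, skipna=True)
    m2 = table.intensities[qc2].median(axis=1, skipna=True)
    factor = m2 / m1
    bad = ~np.isfinite(factor) | (factor <= 0)
    if bad.any():
        log.warning("batch factor undefined for %d feature(s); left unscaled",
                    int(bad.sum()))
        factor = factor.where(~bad, 1.0)
    batch2_cols = meta.index[meta["extraction_batch"] == 2].intersection(table.injection_ids)
    out = table.intensities.copy()
    out[batch2_cols] = out[batch2_cols].div(factor, axis=0)
    return FeatureTable(table.features.copy(), out)


def average_replicates(table: FeatureTable, meta: pd.DataFrame):
    """Average technical and sampling replicates into one row per biological
    sample; concatenate positive- and negative-mode features.

    Returns
    -------
    (pandas.DataFrame, pandas.DataFrame)
        A (biological samples x features) intensity matrix (NaN when a
        sample lacks every injection of a feature's mode) and a per-sample
        metadata frame with columns ``system``, ``year``, ``plot``.
    """
    samples = meta[meta["role"] == "sample"]
    if samples.empty:
        raise ValidationError("no sample-role injections to average")
    blocks = []
    for mode in MODES:
        feat_rows = table.features.index[table.features["mode"] == mode]
        if len(feat_rows) == 0:
            continue
        inj = samples.index[samples["ionization_mode"] == mode].intersection(table.injection_ids)
        sub = table.intensities.loc[feat_rows, inj]
        bio = samples.loc[inj, "biological_sample_id"]
        blocks.append(sub.T.groupby(bio).mean())
    matrix = pd.concat(blocks, axis=1)
    matrix = matrix.reindex(columns=table.features.index.intersection(matrix.columns, sort=False))
    counts = samples.groupby("biological_sample_id").size()
    empty = counts.index.difference(matrix.index)
    if len(empty):
        raise ValidationError(f"biological sample(s) with zero injections: {list(empty[:5])}")
    sm = (samples.groupby("biological_sample_id")[["system", "year", "plot"]]
          .first().loc[matrix.index])
    return matrix, sm


def compute_precision(table: FeatureTable, meta: pd.DataFrame):
    """Per-feature relative standard deviation over extraction-QC injections.

    RSD(%) = 100 * sample SD / mean, per feature over the extraction QCs of
    its ionization mode.  Returns ``(per-feature RSD Series, median RSD)``.
    """
    qc = meta.index[meta["role"] == "extraction_qc"].intersection(table.injection_ids)
    if len(qc) < 2:
        raise ValidationError("need at least two extraction QC injections")
    sub = table.intensities[qc]
    n = sub.notna().sum(axis=1)
    if (n < 2).all():
        raise ValidationError("no feature has two or more QC measurements")
    mean = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=1, skipna=True)
    rsd = 100.0 * sd / mean
    rsd[n < 2] = np.nan
    return rsd, float(rsd.median(skipna=True))
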