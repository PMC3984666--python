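"""Synthetic study generator emulating a two-year, three-system field trial.

The generator reproduces the design of a controlled organic-vs-conventional
cabbage trial analysed by untargeted LC-MS: 3 production systems (C, O1, O2)
x 3 replicate field plots x 2 harvest years = 18 biological samples, with
technical duplicates at the extraction step, sampling duplicates for every
third plot, two extraction batches carrying 6 pooled extraction-QC samples
each, extraction blanks after every 10th sample, and injection QCs every
10th injection.  Positive- and negative-mode peak lists are generated
together (~6,000 features by default).

Feature intensities follow a multiplicative model: a log-normal baseline per
feature, fold-change effects of production system and year on independently
drawn feature subsets, a per-feature batch-2 scaling factor, and log-normal
technical noise.  Instrument "ringing" satellites and blank-borne signals
are injected with full ground-truth bookkeeping so that every downstream
filter and test can be scored against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import FeatureTable, META_COLUMNS, ValidationError

__all__ = ["StudyDesignConfig", "GroundTruth", "generate_study", "inject_ringing"]

SYSTEM_LABELS = ("C", "O1", "O2")

#: fraction of reagent carry-over seen for ordinary features in blanks
_BLANK_CARRYOVER = 0.002
#: quantile above which a feature counts as "high intensity" for ringing
_RINGING_QUANTILE = 0.95
#: hard cap on satellites per parent (instruments show up to ~7)
_MAX_SATELLITES = 7


@dataclass
class StudyDesignConfig:
    """Design and effect-size parameters of the simulated study.

    Defaults mirror the field-trial design: 3 systems x 3 plots x 2 years,
    ~6,000 features across both ionization modes, system fold changes in
    [1.14, 2.53] and year fold changes in [1.18, 6.45] on independently
    drawn feature subsets, and technical noise calibrated to a median QC
    RSD near 18%.
    """

    n_systems: int = 3
    n_plots_per_system: int = 3
    years: tuple = (2007, 2008)
    n_features_pos: int = 4000
    n_features_neg: int = 2000
    frac_system_affected: float = 0.40
    frac_year_affected: float = 0.55
    system_fold_range: tuple = (1.14, 2.53)
    year_fold_range: tuple = (1.18, 6.45)
    cv_technical: float = 0.18
    batch_factor_range: tuple = (0.80, 1.25)
    ringing_rate: float = 2.0
    blank_signal_rate: float = 0.05
    distinct_organic_effects: bool = False
    log10_baseline_range: tuple = (3.5, 6.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_systems < 2 or self.n_systems > len(SYSTEM_LABELS):
            raise ValidationError(f"n_systems must be in [2, {len(SYSTEM_LABELS)}]")
        for name in ("n_plots_per_system", "n_features_pos", "n_features_neg"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive count")
        if len(self.years) < 2:
            raise ValidationError("need at least two year labels")
        for name in ("frac_system_affected", "frac_year_affected", "blank_signal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a fraction in [0, 1], got {v}")
        for name in ("system_fold_range", "year_fold_range"):
            lo, hi = getattr(self, name)
            if lo < 1.0 or hi < lo:
                raise ValidationError(f"{name} must satisfy 1 <= lo <= hi, got {(lo, hi)}")
        lo, hi = self.batch_factor_range
        if lo <= 0 or hi < lo:
            raise ValidationError("batch_factor_range must satisfy 0 < lo <= hi")
        if self.cv_technical < 0 or self.ringing_rate < 0:
            raise ValidationError("cv_technical and ringing_rate must be >= 0")

    @property
    def systems(self) -> tuple:
        return SYSTEM_LABELS[: self.n_systems]

    @property
    def n_biological_samples(self) -> int:
        return self.n_systems * self.n_plots_per_system * len(self.years)


@dataclass
class GroundTruth:
    """Per-feature truth flags and effect sizes of a generated study.

    ``features`` is indexed by feature id with boolean columns
    ``system_affected``, ``year_affected``, ``is_blank_signal``,
    ``is_ringing_satellite``; ``parent_id`` (satellites only);
    ``system_fold`` / ``year_fold`` (magnitude >= 1, NaN when unaffected);
    ``system_multiplier_C`` and ``year_multiplier`` (the multipliers
    actually applied to C samples / second-year samples); and
    ``batch_factor`` (multiplier applied to batch-2 extracts).
    """

    features: pd.DataFrame
    config: StudyDesignConfig | None = None

    def __post_init__(self) -> None:
        sat = self.features["is_ringing_satellite"]
        parents = self.features.loc[sat, "parent_id"]
        missing = [p for p in parents if p not in self.features.index]
        if missing:
            raise ValidationError(f"satellite parent(s) missing from truth: {missing[:5]}")

    @property
    def satellite_ids(self) -> list[str]:
        return list(self.features.index[self.features["is_ringing_satellite"]])

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config) if self.config is not None else None,
            "features": json.loads(self.features.to_json(orient="index")),
            "feature_order": list(self.features.index),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        feats = pd.DataFrame.from_dict(payload["features"], orient="index")
        feats = feats.loc[payload["feature_order"]]
        cfg = payload.get("config")
        return cls(feats, StudyDesignConfig(**{k: tuple(v) if isinstance(v, list) else v
                                               for k, v in cfg.items()}) if cfg else None)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_fold_multipliers(rng, n, affected, fold_range):
    """Magnitude (>=1) and signed multiplier for each affected feature."""
    fold = np.full(n, np.nan)
    mult = np.ones(n)
    idx = np.flatnonzero(affected)
    if idx.size:
        f = rng.uniform(fold_range[0], fold_range[1], size=idx.size)
        up = rng.random(idx.size) < 0.5
        fold[idx] = f
        mult[idx] = np.where(up, f, 1.0 / f)
    return fold, mult


def _extraction_schedule(units: list[str], rng) -> pd.DataFrame:
    """Randomized extraction order with batches, extraction QCs and blanks.

    Each sampling unit is extracted in duplicate (technical replicates);
    replicate 1 goes to batch 1 and replicate 2 to batch 2, so every sample
    is represented equally in both batches and residual batch error cancels
    from all between-sample contrasts.  Order is randomized within a batch;
    one pooled extraction QC follows every 4th sample extract (topped up to
    6 per batch) and one extraction blank follows every 10th.
    """
    rows = []
    qc_serial = blank_serial = 0
    chunks = []
    for rep in (1, 2):
        order = rng.permutation(len(units))
        chunks.append((rep, [(units[i], rep) for i in order]))
    for batch, chunk in ((1, chunks[0][1]), (2, chunks[1][1])):
        n_qc_in_batch = 0
        for i, (unit, rep) in enumerate(chunk, start=1):
            rows.append({"extract_id": f"{unit}.t{rep}", "role": "sample",
                         "unit": unit, "technical_replicate": rep, "batch": batch})
            if i % 4 == 0:
                qc_serial += 1
                n_qc_in_batch += 1
                rows.append({"extract_id": f"EQC{qc_serial:02d}", "role": "extraction_qc",
                             "unit": None, "technical_replicate": qc_serial, "batch": batch})
            if i % 10 == 0:
                blank_serial += 1
                rows.append({"extract_id": f"BLK{blank_serial:02d}", "role": "extraction_blank",
                             "unit": None, "technical_replicate": blank_serial, "batch": batch})
        while n_qc_in_batch < 6:
            qc_serial += 1
            n_qc_in_batch += 1
            rows.append({"extract_id": f"EQC{qc_serial:02d}", "role": "extraction_qc",
                         "unit": None, "technical_replicate": qc_serial, "batch": batch})
    return pd.DataFrame(rows)


def generate_study(config: StudyDesignConfig):
    """Generate a full synthetic study.

    Returns
    -------
    (FeatureTable, pandas.DataFrame, GroundTruth)
        The feature table (both modes, ringing satellites included), the
        injection metadata frame indexed by injection id, and the ground
        truth.  Bit-reproducible for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    systems = config.systems
    years = tuple(config.years)

    # -- feature annotations ------------------------------------------------
    n_pos, n_neg = config.n_features_pos, config.n_features_neg
    n_feat = n_pos + n_neg
    ids = [f"P{i + 1:05d}" for i in range(n_pos)] + [f"N{i + 1:05d}" for i in range(n_neg)]
    modes = np.array(["pos"] * n_pos + ["neg"] * n_neg)
    mz = rng.uniform(50.0, 1700.0, size=n_feat)
    rt = rng.uniform(20.0, 900.0, size=n_feat)
    lo, hi = config.log10_baseline_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=n_feat)

    # -- truth flags and effect sizes --------------------------------------
    is_blank = rng.random(n_feat) < config.blank_signal_rate
    sys_aff = (rng.random(n_feat) < config.frac_system_affected) & ~is_blank
    year_aff = (rng.random(n_feat) < config.frac_year_affected) & ~is_blank
    sys_fold, sys_mult_C = _draw_fold_multipliers(rng, n_feat, sys_aff, config.system_fold_range)
    year_fold, year_mult = _draw_fold_multipliers(rng, n_feat, year_aff, config.year_fold_range)
    if config.distinct_organic_effects:
        _, sys_mult_O2 = _draw_fold_multipliers(rng, n_feat, sys_aff, config.system_fold_range)
    else:
        sys_mult_O2 = np.ones(n_feat)
    batch_factor = rng.uniform(*config.batch_factor_range, size=n_feat)

    # per-(feature, system, year) expected multiplier relative to baseline
    sys_mult = {s: np.ones(n_feat) for s in systems}
    sys_mult["C"] = sys_mult_C
    if config.distinct_organic_effects and "O2" in sys_mult:
        sys_mult["O2"] = sys_mult_O2
    year_mult_by_year = {y: np.ones(n_feat) for y in years}
    for y in years[1:]:
        year_mult_by_year[y] = year_mult

    # -- sampling units ------------------------------------------------------
    units: list[str] = []           # one entry per sampling unit
    unit_bio: dict[str, str] = {}   # sampling unit -> biological sample id
    unit_dup: dict[str, bool] = {}
    unit_sys: dict[str, str] = {}
    unit_year: dict[str, object] = {}
    unit_plot: dict[str, int] = {}
    for year in years:
        for s in systems:
            for plot in range(1, config.n_plots_per_system + 1):
                bio = f"{s}{plot}-{year}"
                n_samplings = 2 if plot % 3 == 0 else 1  # duplicate every 3rd plot
                for k in range(1, n_samplings + 1):
                    unit = bio if k == 1 else f"{bio}.s2"
                    units.append(unit)
                    unit_bio[unit] = bio
                    unit_dup[unit] = k > 1
                    unit_sys[unit] = s
                    unit_year[unit] = year
                    unit_plot[unit] = plot

    # expected (noise-free) intensity per feature for each sampling unit
    unit_expected = {
        u: baseline * sys_mult[unit_sys[u]] * year_mult_by_year[unit_year[u]]
        for u in units
    }
    # blank-borne signals sit at their baseline level in everything
    for u in units:
        unit_expected[u] = np.where(is_blank, baseline, unit_expected[u])
    # pooled cabbage QC: mean over the 18 biological units (duplicates excluded)
    pool = np.mean([unit_expected[u] for u in units if not unit_dup[u]], axis=0)
    blank_expected = np.where(is_blank, baseline, _BLANK_CARRYOVER * baseline)

    # -- extraction schedule and injection sequence -------------------------
    schedule = _extraction_schedule(units, rng)
    sigma = float(np.sqrt(np.log1p(config.cv_technical ** 2)))

    meta_rows = []
    columns: dict[str, np.ndarray] = {}
    mode_mask = {"pos": modes == "pos", "neg": modes == "neg"}
    for mode in ("pos", "neg"):
        inj_order = rng.permutation(len(schedule))
        serial = 0
        n_injected = 0
        for j in inj_order:
            row = schedule.iloc[j]
            n_injected += 1
            if n_injected % 10 == 0:  # every 10th injection is an injection QC
                serial += 1
                iid = f"{mode[0].upper()}{serial:03d}"
                expected = pool * (1.0 + batch_factor) / 2.0  # pool spans both batches
                meta_rows.append({
                    "injection_id": iid, "biological_sample_id": "POOL",
                    "role": "injection_qc", "system": None, "year": None,
                    "plot": None, "extraction_batch": None,
                    "technical_replicate": serial, "sampling_duplicate": False,
                    "ionization_mode": mode,
                })
                columns[iid] = _noisy(expected, sigma, rng, mode_mask[mode], n_feat)
            serial += 1
            iid = f"{mode[0].upper()}{serial:03d}"
            if row["role"] == "sample":
                unit = row["unit"]
                expected = unit_expected[unit]
                bio, sys_, yr, plot = unit_bio[unit], unit_sys[unit], unit_year[unit], unit_plot[unit]
                dup = unit_dup[unit]
            elif row["role"] == "extraction_qc":
                expected = pool
                bio, sys_, yr, plot, dup = "QCPOOL", None, None, None, False
            else:  # extraction blank
                expected = blank_expected
                bio, sys_, yr, plot, dup = "BLANK", None, None, None, False
            if row["batch"] == 2:
                expected = expected * batch_factor
            meta_rows.append({
                "injection_id": iid, "biological_sample_id": bio, "role": row["role"],
                "system": sys_, "year": yr, "plot": plot,
                "extraction_batch": int(row["batch"]),
                "technical_replicate": int(row["technical_replicate"]),
                "sampling_duplicate": bool(dup), "ionization_mode": mode,
            })
            columns[iid] = _noisy(expected, sigma, rng, mode_mask[mode], n_feat)

    features = pd.DataFrame({"mode": modes, "mz": mz, "rt_s": rt}, index=pd.Index(ids, name="feature_id"))
    intensities = pd.DataFrame(columns, index=features.index)
    table = FeatureTable(features, intensities)
    meta = pd.DataFrame(meta_rows).set_index("injection_id")[list(META_COLUMNS)]
    for col in ("plot", "extraction_batch", "technical_replicate"):
        meta[col] = meta[col].astype("Int64")
    if all(isinstance(y, (int, np.integer)) for y in years):
        meta["year"] = meta["year"].astype("Int64")

    truth_feats = pd.DataFrame({
        "system_affected": sys_aff, "year_affected": year_aff,
        "is_blank_signal": is_blank, "is_ringing_satellite": False,
        "parent_id": "", "system_fold": sys_fold, "year_fold": year_fold,
        "system_multiplier_C": sys_mult_C, "year_multiplier": year_mult,
        "batch_factor": batch_factor,
    }, index=features.index)

    if config.ringing_rate > 0:
        ring_seed = int(rng.integers(0, 2 ** 31 - 1))
        table, sat_truth = inject_ringing(table, config.ringing_rate, ring_seed)
        truth_feats = pd.concat([truth_feats, sat_truth])

    return table, meta, GroundTruth(truth_feats, config)


def _noisy(expected, sigma, rng, mask, n_feat):
    col = np.full(n_feat, np.nan)
    noise = np.exp(rng.normal(0.0, sigma, size=int(mask.sum()))) if sigma > 0 else 1.0
    col[mask] = expected[mask] * noise
    return col


def inject_ringing(table: FeatureTable, rate: float, seed: int):
    """Add ringing-satellite features to high-intensity peaks.

    For features above the 95th intensity percentile of their mode, a
    Poisson(``rate``)-distributed number of satellites (capped at 7) is
    appended at m/z offsets drawn strictly inside (+0.01, +0.2) amu,
    retention-time offsets within +-0.5 s, and intensities at 2-10% of the
    parent, mirroring the parent's intensity pattern across injections.

    Returns the augmented table and a truth frame for the satellites
    (``rate=0`` returns the table unchanged with an empty truth frame).
    """
    if rate < 0:
        raise ValidationError("ringing rate must be >= 0")
    empty = pd.DataFrame(columns=["system_affected", "year_affected", "is_blank_signal",
                                  "is_ringing_satellite", "parent_id", "system_fold",
                                  "year_fold", "system_multiplier_C", "year_multiplier",
                                  "batch_factor"])
    if rate == 0 or table.n_features == 0:
        return table, empty
    rng = np.random.default_rng(seed)
    ref = table.intensities.median(axis=1, skipna=True)
    new_feats, new_rows, truth_rows = [], [], []
    for mode in ("pos", "neg"):
        in_mode = table.features["mode"] == mode
        if not in_mode.any():
            continue
        cutoff = ref[in_mode].quantile(_RINGING_QUANTILE)
        parents = ref.index[in_mode & (ref >= cutoff)]
        for pid in parents:
            k = min(int(rng.poisson(rate)), _MAX_SATELLITES)
            for j in range(1, k + 1):
                sid = f"{pid}.r{j}"
                dmz = rng.uniform(0.011, 0.199)
                drt = rng.uniform(-0.45, 0.45)
                frac = rng.uniform(0.02, 0.10)
                new_feats.append({"feature_id": sid, "mode": mode,
                                  "mz": table.features.at[pid, "mz"] + dmz,
                                  "rt_s": max(table.features.at[pid, "rt_s"] + drt, 0.0)})
                new_rows.append(table.intensities.loc[pid].to_numpy() * frac)
                truth_rows.append({"feature_id": sid, "system_affected": False,
                                   "year_affected": False, "is_blank_signal": False,
                                   "is_ringing_satellite": True, "parent_id": pid,
                                   "system_fold": np.nan, "year_fold": np.nan,
                                   "system_multiplier_C": 1.0, "year_multiplier": 1.0,
                                   "batch_factor": np.nan})
    if not new_feats:
        return table, empty
    sat_feats = pd.DataFrame(new_feats).set_index("feature_id")
    sat_int = pd.DataFrame(np.vstack(new_rows), index=sat_feats.index,
                           columns=table.intensities.columns)
    out = FeatureTable(pd.concat([table.features, sat_feats]),
                       pd.concat([table.intensities, sat_int]))
    truth = pd.DataFrame(truth_rows).set_index("feature_id")
    return out, truth
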