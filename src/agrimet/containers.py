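"""Core data containers for aligned LC-MS feature tables and injection metadata.

A :class:`FeatureTable` holds one aligned peak list per study: a per-feature
annotation frame (ionization mode, m/z in amu, retention time in seconds) and
an intensity matrix of shape (features x injections).  Positive- and
negative-mode features live in one table; an injection acquired in one mode
carries NaN for the other mode's features.  Missing measurements are always
NaN, never zero.

Injection metadata is a plain :class:`pandas.DataFrame` indexed by
injection id and validated by :func:`validate_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = frozenset({"sample", "extraction_qc", "extraction_blank", "injection_qc"})
SYSTEMS = frozenset({"C", "O1", "O2"})
MODES = ("pos", "neg")

#: columns required in an injection metadata frame
META_COLUMNS = (
    "biological_sample_id",
    "role",
    "system",
    "year",
    "plot",
    "extraction_batch",
    "technical_replicate",
    "sampling_duplicate",
    "ionization_mode",
)


class ValidationError(ValueError):
    """Raised when a table or metadata frame violates its invariants."""


@dataclass
class FeatureTable:
    """Aligned feature table: annotations plus an intensity matrix.

    Parameters
    ----------
    features:
        DataFrame indexed by feature id with columns ``mode`` ('pos'|'neg'),
        ``mz`` (amu, > 0) and ``rt_s`` (seconds, >= 0).
    intensities:
        DataFrame indexed by feature id (same order as ``features``) with one
        column per injection id.  Values are finite and >= 0, or NaN for
        missing / off-mode cells.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        f = self.features
        for col in ("mode", "mz", "rt_s"):
            if col not in f.columns:
                raise ValidationError(f"feature frame missing column {col!r}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature_id: {dups[:5]}")
        if not f.index.equals(self.intensities.index):
            raise ValidationError("features and intensities must share one index")
        if self.intensities.columns.has_duplicates:
            raise ValidationError("duplicate injection_id in intensity matrix")
        if len(f) == 0:
            return
        if not f["mode"].isin(MODES).all():
            bad = sorted(set(f["mode"]) - set(MODES))
            raise ValidationError(f"unknown ionization mode(s) {bad}; allowed: {MODES}")
        if not (f["mz"] > 0).all():
            raise ValidationError("all m/z values must be > 0")
        if not (f["rt_s"] >= 0).all():
            raise ValidationError("all retention times must be >= 0")
        vals = self.intensities.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (not np.isfinite(finite).all() or (finite < 0).any()):
            raise ValidationError("intensities must be finite and >= 0 (NaN = missing)")

    # -- convenience --------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_injections(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def injection_ids(self) -> pd.Index:
        return self.intensities.columns

    def mode_counts(self) -> dict[str, int]:
        return {m: int((self.features["mode"] == m).sum()) for m in MODES}

    def subset(self, feature_ids) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (order preserved)."""
        idx = self.features.index.intersection(pd.Index(feature_ids), sort=False)
        return FeatureTable(self.features.loc[idx].copy(), self.intensities.loc[idx].copy())

    def drop(self, feature_ids) -> "FeatureTable":
        keep = self.features.index.difference(pd.Index(feature_ids), sort=False)
        return self.subset(keep)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.copy())


def validate_metadata(meta: pd.DataFrame, table: FeatureTable | None = None) -> pd.DataFrame:
    """Validate an injection metadata frame, optionally against a table.

    Checks the role / system / mode vocabularies, uniqueness of injection
    ids, and batch labels for sample and extraction-QC injections.  Returns
    the frame unchanged so the call composes.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s) {missing}")
    if meta.index.has_duplicates:
        raise ValidationError("duplicate injection_id in metadata")
    bad_roles = sorted(set(meta["role"]) - ROLES)
    if bad_roles:
        raise ValidationError(
            f"unknown role(s) {bad_roles}; allowed: {sorted(ROLES)}"
        )
    samples = meta[meta["role"] == "sample"]
    bad_sys = sorted(set(samples["system"].dropna()) - SYSTEMS)
    if bad_sys:
        raise ValidationError(
            f"unknown system label(s) {bad_sys}; allowed: {sorted(SYSTEMS)}"
        )
    if not meta["ionization_mode"].isin(MODES).all():
        raise ValidationError(f"ionization_mode must be one of {MODES}")
    needs_batch = meta["role"].isin(["sample", "extraction_qc"])
    if meta.loc[needs_batch, "extraction_batch"].isna().any():
        raise ValidationError("sample and extraction_qc injections need a batch label")
    # every sample injection maps to exactly one (system, year, plot)
    grp = samples.groupby("biological_sample_id")[["system", "year", "plot"]].nunique()
    if (grp > 1).any().any():
        raise ValidationError("a biological sample maps to more than one (system, year, plot)")
    if table is not None:
        extra = meta.index.difference(table.injection_ids)
        if len(extra):
            import warnings

            warnings.warn(
                f"{len(extra)} metadata injection(s) absent from the feature table "
                "(retained)",
                stacklevel=2,
            )
    return meta


@dataclass
class CleaningReport:
    """Bookkeeping for one feature-removal rule.

    ``before - removed == after`` holds per ionization mode.
    """

    rule: str
    removed: dict[str, str] = field(default_factory=dict)  # feature_id -> reason
    before_per_mode: dict[str, int] = field(default_factory=dict)
    after_per_mode: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def check(self) -> None:
        removed_modes: dict[str, int] = {}
        for m in self.before_per_mode:
            removed_modes[m] = self.before_per_mode[m] - self.after_per_mode.get(m, 0)
        if sum(removed_modes.values()) != self.n_removed:
            raise ValidationError("cleaning report counts are inconsistent")

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_removed": self.n_removed,
            "before_per_mode": self.before_per_mode,
            "after_per_mode": self.after_per_mode,
            "removed": self.removed,
        }
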