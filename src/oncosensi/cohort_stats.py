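"""Frozen-reference Z-scoring of cohort features.

Each feature is standardized as (transform(x) - mean) / sd with the mean
and sample SD (n-1) frozen on a reference cohort (the 14-patient test
set); external validation cohorts are always scored against those frozen
statistics, never refit.  Growth rate is standardized on the natural-log
scale and dose-response AUC on the raw scale -- the unique combination
consistent with the published per-patient Z columns.  HPV status is coded
positive=1 / negative=0 and then standardized like any other feature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: feature name -> transform applied before standardization
DEFAULT_TRANSFORMS: dict[str, str] = {
    "rt_auc": "identity",
    "growth_rate": "log",
    "hpv": "identity",
}

_TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
}


def code_hpv(status) -> float:
    """HPV label -> 0/1 (positive=1, negative=0); missing -> NaN."""
    if isinstance(status, str):
        s = status.strip().lower()
        if s == "positive":
            return 1.0
        if s == "negative":
            return 0.0
        raise ValueError(f"unknown HPV status {status!r}")
    if status is None or (isinstance(status, float) and math.isnan(status)):
        return float("nan")
    if status in (0, 1):
        return float(status)
    raise ValueError(f"unknown HPV status {status!r}")


@dataclass(frozen=True)
class FeatureStats:
    transform: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class CohortReferenceStats:
    """Per-feature transform + frozen mean/SD of the reference cohort."""

    features: dict[str, FeatureStats]

    def __getitem__(self, feature: str) -> FeatureStats:
        return self.features[feature]

    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = {
            name: {"transform": fs.transform, "mean": fs.mean, "sd": fs.sd, "n": fs.n}
            for name, fs in self.features.items()
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: "str | Path") -> "CohortReferenceStats":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(features={
            name: FeatureStats(d["transform"], d["mean"], d["sd"], int(d["n"]))
            for name, d in payload.items()
        })


def _feature_values(records: pd.DataFrame, feature: str) -> np.ndarray:
    if feature == "hpv":
        return np.array([code_hpv(v) for v in records["hpv"]], dtype=float)
    return records[feature].to_numpy(dtype=float)


def freeze_reference(
    records: pd.DataFrame,
    transforms: "dict[str, str] | None" = None,
) -> CohortReferenceStats:
    """Freeze per-feature mean and sample SD on the reference cohort.

    Rows with a missing value of a feature (e.g. unknown HPV status) are
    excluded from that feature's statistics only.
    """
    transforms = dict(DEFAULT_TRANSFORMS) if transforms is None else transforms
    if len(records) < 2:
        raise ValueError("need at least two reference records")
    out: dict[str, FeatureStats] = {}
    for feature, tname in transforms.items():
        tf = _TRANSFORMS[tname]
        raw = _feature_values(records, feature)
        raw = raw[~np.isnan(raw)]
        if tname == "log" and np.any(raw <= 0):
            raise ValueError(f"log transform of non-positive {feature} value")
        vals = tf(raw)
        sd = float(np.std(vals, ddof=1))
        if sd == 0:
            raise ValueError(f"feature {feature} is constant in the reference cohort")
        out[feature] = FeatureStats(tname, float(np.mean(vals)), sd, int(vals.size))
    return CohortReferenceStats(features=out)


def zscore(value, stats: CohortReferenceStats, feature: str):
    """(transform(value) - frozen mean) / frozen SD; scalar or array."""
    fs = stats[feature]
    tf = _TRANSFORMS[fs.transform]
    arr = np.asarray(value, dtype=float)
    if fs.transform == "log" and np.any(arr <= 0):
        raise ValueError("log transform of non-positive value")
    z = (tf(arr) - fs.mean) / fs.sd
    return float(z) if np.isscalar(value) or arr.ndim == 0 else z


def standardize_cohort(
    records: pd.DataFrame,
    stats: CohortReferenceStats,
) -> pd.DataFrame:
    """Z-score columns for every feature carried by ``stats``.

    Works identically for the reference cohort and external validation
    cohorts -- the frozen statistics are applied, never refit.  Returns a
    DataFrame with one ``z_<feature>`` column per feature (NaN where the
    raw value is missing).
    """
    out = {}
    for feature, fs in stats.features.items():
        raw = _feature_values(records, feature)
        z = np.full(raw.shape, np.nan)
        ok = ~np.isnan(raw)
        z[ok] = zscore(raw[ok], stats, feature)
        out[f"z_{feature}"] = z
    return pd.DataFrame(out, index=records.index)


def apply_to_validation(
    validation_records: pd.DataFrame,
    frozen_stats: CohortReferenceStats,
) -> pd.DataFrame:
    """Score an external validation cohort against frozen reference stats."""
    return standardize_cohort(validation_records, frozen_stats)
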