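"""Daily state-matrix construction from raw event tables.

Raw timestamped observations are binned into consecutive 24 h windows from
sepsis onset. Frequently sampled measurements contribute mean/max/min/sd
aggregates with forward-fill imputation; drug administrations contribute
the 24 h cumulative sum with zero-fill. Variables observed on at most a
configurable fraction of training admission-days are dropped, and all
features are min-max normalized to [-1, +1] with bounds fitted on the
training split only (values outside the fitted range are clipped).

Which variables are "frequently sampled measurements" versus "drugs" is
declared in a shipped registry rather than inferred from the data, so a
given registry always yields the same state-vector layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MEASUREMENT_AGGS = ("mean", "max", "min", "sd")


@dataclass(frozen=True)
class FeatureSpec:
    variable_name: str
    kind: str                       # "measurement" | "drug"
    aggregations: tuple
    impute_rule: str                # "forward_fill" | "zero_fill"

    def __post_init__(self):
        if self.kind == "measurement":
            assert set(self.aggregations) <= set(MEASUREMENT_AGGS)
            assert self.impute_rule == "forward_fill"
        elif self.kind == "drug":
            assert self.aggregations == ("sum",)
            assert self.impute_rule == "zero_fill"
        else:
            raise ValueError(f"unknown feature kind {self.kind!r}")


def _measurement(name):
    return FeatureSpec(name, "measurement", MEASUREMENT_AGGS, "forward_fill")


def _drug(name):
    return FeatureSpec(name, "drug", ("sum",), "zero_fill")


#: Shipped registry for the synthetic panel. Corticosteroid compounds and
#: culture events are deliberately absent: the administered steroid dose is
#: the action, not part of the state, and mortality is the reward.
DEFAULT_REGISTRY = {spec.variable_name: spec for spec in [
    _measurement("heart_rate"),
    _measurement("mean_arterial_pressure"),
    _measurement("respiratory_rate"),
    _measurement("temperature"),
    _measurement("gcs"),
    _measurement("lactate"),
    _measurement("creatinine"),
    _measurement("platelets"),
    _measurement("bilirubin"),
    _measurement("leukocytes"),
    _measurement("glucose"),
    _measurement("sodium"),
    _measurement("pao2_fio2_ratio"),
    _measurement("urine_output"),
    _drug("norepinephrine"),
    _drug("antibiotic"),
    _drug("ventilated"),
]}


@dataclass
class DailyState:
    """One ICU day's aggregated, imputed, normalized feature vector."""
    admission_id: str
    day_index: int                  # days since sepsis onset, 0-based
    features: np.ndarray
    feature_names: list
    observed_mask: np.ndarray       # pre-imputation availability


def column_names(registry) -> list:
    cols = []
    for name in sorted(registry):
        for agg in registry[name].aggregations:
            cols.append(f"{name}__{agg}")
    return cols


def bin_and_aggregate(events: pd.DataFrame, episodes, admissions: pd.DataFrame,
                      registry=None) -> pd.DataFrame:
    """Aggregate events into a raw daily table for included episodes.

    Returns a DataFrame indexed by (admission_id, day_index since onset)
    with one column per variable-aggregation pair; cells with no
    observation that day are NaN. The sd aggregate uses the population
    convention (sd of a single observation is 0).
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    included = [e for e in episodes if e.included]
    onset = {e.admission_id: e.onset_day for e in included}
    n_days = {e.admission_id: e.last_day - e.onset_day + 1 for e in included}
    cols = column_names(registry)
    index = pd.MultiIndex.from_tuples(
        [(a, d) for a in sorted(onset) for d in range(n_days[a])],
        names=["admission_id", "day_index"])
    if not len(events) or not included:
        return pd.DataFrame(np.nan, index=index, columns=cols)

    adm = admissions.set_index("admission_id")
    ev = events[events["variable_name"].isin(registry)
                & events["admission_id"].isin(onset)].copy()
    ev["admission_id"] = ev["admission_id"].astype(str)
    admitted = adm.loc[ev["admission_id"], "admitted_at"].to_numpy()
    hours = (ev["timestamp"].to_numpy() - admitted) / np.timedelta64(1, "h")
    abs_day = np.floor(hours / 24.0).astype(int)
    ev["day_index"] = abs_day - ev["admission_id"].map(onset).to_numpy()
    ev = ev[(ev["day_index"] >= 0)
            & (ev["day_index"] < ev["admission_id"].map(n_days).to_numpy())]

    pieces = []
    grouped = ev.groupby(["admission_id", "day_index", "variable_name"])["numeric_value"]
    aggs = grouped.agg(mean="mean", max="max", min="min",
                       sd=lambda v: float(np.std(v, ddof=0)), sum="sum")
    for name, spec in registry.items():
        try:
            sub = aggs.xs(name, level="variable_name")
        except KeyError:
            continue
        keep = sub[list(spec.aggregations)]
        keep.columns = [f"{name}__{a}" for a in spec.aggregations]
        pieces.append(keep)
    raw = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=index)
    raw = raw.reindex(index=index, columns=cols)
    assert not raw.index.duplicated().any()
    return raw


def filter_coverage(raw: pd.DataFrame, train_ids, threshold: float = 0.02,
                    registry=None):
    """Drop variables observed on at most ``threshold`` of training
    admission-days. Returns (reduced table, dropped variable list).

    Coverage is computed on the training-split rows only so validation and
    test data can never influence which variables survive.
    """
    if not (0 <= threshold < 1):
        raise ValueError("coverage threshold must lie in [0, 1)")
    registry = DEFAULT_REGISTRY if registry is None else registry
    train = raw.loc[raw.index.get_level_values(0).isin(set(train_ids))]
    dropped = []
    keep_cols = []
    for name in sorted(registry):
        spec = registry[name]
        cols = [f"{name}__{a}" for a in spec.aggregations if f"{name}__{a}" in raw.columns]
        if not cols:
            continue
        frac = float(train[cols[0]].notna().mean()) if len(train) else 0.0
        if frac > threshold:
            keep_cols.extend(cols)
        else:
            dropped.append(name)
    return raw[keep_cols], dropped


def impute(table: pd.DataFrame, train_ids=None, registry=None):
    """Complete the raw daily table.

    Measurement aggregates are forward-filled within each admission (never
    across admissions); missing drug sums become 0; gaps before a
    variable's first observation are filled with the training-split median.
    Returns (completed table, observed mask, imputed_fraction).
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    observed = table.notna()
    train_rows = (table if train_ids is None else
                  table.loc[table.index.get_level_values(0).isin(set(train_ids))])
    medians = train_rows.median()
    out = table.copy()
    drug_cols = [c for c in out.columns
                 if registry[c.split("__")[0]].impute_rule == "zero_fill"]
    meas_cols = [c for c in out.columns if c not in drug_cols]
    if drug_cols:
        out[drug_cols] = out[drug_cols].fillna(0.0)
    if meas_cols:
        out[meas_cols] = out[meas_cols].groupby(level=0, sort=False).ffill()
        lead = medians.reindex(meas_cols).fillna(0.0)
        out[meas_cols] = out[meas_cols].fillna(lead)
    total = out.size
    imputed_fraction = float((~observed).to_numpy().sum() / total) if total else 0.0
    assert not out.isna().any().any()
    return out, observed, imputed_fraction


@dataclass
class NormalizationBounds:
    low: pd.Series
    high: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        lo = self.low.reindex(table.columns)
        hi = self.high.reindex(table.columns)
        span = hi - lo
        const = span <= 0
        scaled = 2.0 * (table - lo) / span.where(~const, 1.0) - 1.0
        scaled.loc[:, const[const].index] = 0.0
        return scaled.clip(-1.0, 1.0)

    def inverse(self, scaled: pd.DataFrame) -> pd.DataFrame:
        lo = self.low.reindex(scaled.columns)
        hi = self.high.reindex(scaled.columns)
        return (scaled + 1.0) / 2.0 * (hi - lo) + lo


def normalize(table: pd.DataFrame, train_ids=None,
              bounds: NormalizationBounds | None = None):
    """Min-max normalize every feature to [-1, +1].

    Bounds are fitted on the training rows only; out-of-range values in
    validation/test rows are clipped; constant variables map to 0. Returns
    (normalized table, bounds).
    """
    if bounds is None:
        train_rows = (table if train_ids is None else
                      table.loc[table.index.get_level_values(0).isin(set(train_ids))])
        bounds = NormalizationBounds(low=train_rows.min(), high=train_rows.max())
    return bounds.transform(table), bounds


def to_daily_states(normalized: pd.DataFrame, observed: pd.DataFrame) -> list:
    names = list(normalized.columns)
    states = []
    for (adm_id, day), row in normalized.iterrows():
        states.append(DailyState(
            admission_id=str(adm_id), day_index=int(day),
            features=row.to_numpy(dtype=float), feature_names=names,
            observed_mask=observed.loc[(adm_id, day)].to_numpy(dtype=bool)))
    return states


@dataclass
class FeaturePipeline:
    """Fitted feature pipeline: coverage decisions, training medians and
    normalization bounds, reusable verbatim at inference time."""

    registry: dict = field(default_factory=lambda: dict(DEFAULT_REGISTRY))
    coverage_threshold: float = 0.02
    dropped: list = field(default_factory=list)
    bounds: NormalizationBounds | None = None
    imputed_fraction: float = float("nan")

    def fit_transform(self, events, episodes, admissions, train_ids):
        raw = bin_and_aggregate(events, episodes, admissions, self.registry)
        raw, self.dropped = filter_coverage(raw, train_ids,
                                            self.coverage_threshold, self.registry)
        completed, observed, self.imputed_fraction = impute(
            raw, train_ids, self.registry)
        normalized, self.bounds = normalize(completed, train_ids)
        return normalized, observed

    def to_json(self) -> str:
        return json.dumps({
            "coverage_threshold": self.coverage_threshold,
            "dropped": self.dropped,
            "imputed_fraction": self.imputed_fraction,
            "low": {} if self.bounds is None else self.bounds.low.to_dict(),
            "high": {} if self.bounds is None else self.bounds.high.to_dict(),
        }, indent=2)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())
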