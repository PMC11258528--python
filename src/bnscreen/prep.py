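"""Data preparation: outcome construction, split, filters, binning, encoding.

The preparation pipeline mirrors common practice for survey-based screening
models: respondents are randomly split 70/30 into training and test; the
binary outcome is the PHQ-9 sum at cut-off ≥10 (respondents must have
answered all nine items and be adults); depression-related columns, columns
and respondents with more than 20 % missing values, and single-level
columns are dropped; numeric columns with more than 30 distinct values are
quartile-binned; everything is ordinally encoded with a dedicated missing
class at code 0; and features are z-standardized for the linear classifier
(structure learning keeps the discrete codes).

All fitted artifacts — quartile edges, encoding maps, standardization
statistics — derive from the training partition only and are reused on the
test partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ColumnMeta, SurveyDataset


@dataclass
class PrepConfig:
    train_fraction: float = 0.70
    phq9_cutoff: int = 10
    min_age: int = 18
    missing_feature_threshold: float = 0.20
    missing_respondent_threshold: float = 0.20
    highcard_level_threshold: int = 30
    n_bins: int = 4
    missing_code: int = 0
    age_column: str = "age"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")
        for name in ("missing_feature_threshold", "missing_respondent_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be ≥ 2")


@dataclass
class StandardizationStats:
    """Per-feature training mean and standard deviation."""

    mean: pd.Series
    sd: pd.Series


# ---------------------------------------------------------------------------
# outcome
# ---------------------------------------------------------------------------

def compute_outcome(phq9_items, age: float | None, cfg: PrepConfig | None = None):
    """Outcome for one respondent: 1 if the PHQ-9 sum ≥ cutoff, 0 otherwise.

    Returns ``None`` (excluded) when any of the nine items is missing or the
    respondent is younger than ``min_age``. Item scores must be 0–3.
    """
    cfg = cfg or PrepConfig()
    items = [np.nan if v is None else float(v) for v in phq9_items]
    if len(items) != 9:
        raise ValueError("exactly 9 PHQ-9 items required")
    observed = [v for v in items if not np.isnan(v)]
    if any(v not in (0.0, 1.0, 2.0, 3.0) for v in observed):
        raise ValueError("PHQ-9 item scores must be in {0,1,2,3}")
    if len(observed) < 9:
        return None
    if age is not None and not np.isnan(age) and age < cfg.min_age:
        return None
    return int(sum(observed) >= cfg.phq9_cutoff)


def build_outcome(data: SurveyDataset, cfg: PrepConfig) -> SurveyDataset:
    """Vectorized outcome construction; excluded respondents are dropped.

    The PHQ-9 item columns are removed afterwards — they define the target
    and must never re-enter the feature set.
    """
    items = data.frame[data.phq9_columns]
    if items.shape[1] != 9:
        raise ValueError(f"expected 9 phq9_item columns, found {items.shape[1]}")
    observed = items.to_numpy(dtype=float)
    valid = ~np.isnan(observed)
    in_range = np.where(valid, np.isin(observed, [0.0, 1.0, 2.0, 3.0]), True)
    if not in_range.all():
        raise ValueError("PHQ-9 item scores must be in {0,1,2,3}")
    complete = valid.all(axis=1)
    keep = complete
    if cfg.age_column in data.frame.columns:
        age = data.frame[cfg.age_column].to_numpy(dtype=float)
        keep = keep & ~(age < cfg.min_age)  # NaN age passes (no evidence of minority)
    sums = np.nansum(observed, axis=1)
    outcome = (sums >= cfg.phq9_cutoff).astype(int)
    kept = data.select_rows(pd.Series(keep, index=data.frame.index))
    kept.outcome = pd.Series(outcome[keep], index=kept.frame.index, name="outcome")
    return kept.drop_columns(data.phq9_columns)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def split_train_test(data: SurveyDataset, cfg: PrepConfig) -> tuple[SurveyDataset, SurveyDataset]:
    """Uniformly random disjoint, exhaustive split; train size = floor(n·f)."""
    n = data.n
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * cfg.train_fraction))
    idx = data.frame.index.to_numpy()
    return data.select_rows(idx[perm[:n_train]]), data.select_rows(idx[perm[n_train:]])


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _modeled_columns(data: SurveyDataset) -> list[str]:
    return data.columns_with_role("feature", "depression_related")


def filter_columns_and_rows(data: SurveyDataset, cfg: PrepConfig):
    """Apply the four drop rules in their fixed order, with a full report.

    1. depression-related columns (by role); 2. columns with missing
    fraction strictly above the threshold; 3. rows with missing fraction
    strictly above the threshold over the remaining modeled columns;
    4. columns with exactly one observed level. Identifier columns are
    exempt. Returns ``(filtered, report)``.
    """
    report = {"columns": [], "rows_dropped": 0, "original_columns": list(data.frame.columns)}
    out = data

    dep = out.columns_with_role("depression_related")
    for c in dep:
        report["columns"].append({"name": c, "rule": "depression_related"})
    out = out.drop_columns(dep)

    modeled = _modeled_columns(out)
    frac = out.frame[modeled].isna().mean()
    high = [c for c in modeled if frac[c] > cfg.missing_feature_threshold]
    for c in high:
        report["columns"].append({"name": c, "rule": "missing_fraction", "fraction": float(frac[c])})
    out = out.drop_columns(high)

    modeled = _modeled_columns(out)
    if modeled:
        row_frac = out.frame[modeled].isna().mean(axis=1)
        keep = row_frac <= cfg.missing_respondent_threshold
        report["rows_dropped"] = int((~keep).sum())
        out = out.select_rows(keep)

    modeled = _modeled_columns(out)
    single = [c for c in modeled if out.frame[c].dropna().nunique() <= 1]
    for c in single:
        report["columns"].append({"name": c, "rule": "single_level"})
    out = out.drop_columns(single)

    if not _modeled_columns(out):
        raise ValueError("all modeled columns were dropped")
    report["retained_columns"] = list(out.frame.columns)
    return out, report


# ---------------------------------------------------------------------------
# quartile binning
# ---------------------------------------------------------------------------

def bin_high_cardinality(data: SurveyDataset, cfg: PrepConfig, edges: dict | None = None):
    """Quartile-bin numeric columns with more than 30 distinct observed values.

    Bin edges are the 25/50/75th percentiles of the *training* data
    (right-closed intervals); pass the returned ``edges`` back in to apply
    the same edges to the test partition. Bins are coded 1..n_bins.
    """
    out = data.copy()
    fitting = edges is None
    edges = {} if fitting else dict(edges)
    for c in _modeled_columns(out):
        if out.meta[c].dtype != "numeric":
            continue
        col = out.frame[c].to_numpy(dtype=float)
        if fitting:
            if pd.Series(col).dropna().nunique() <= cfg.highcard_level_threshold:
                continue
            qs = np.linspace(0, 100, cfg.n_bins + 1)[1:-1]
            edges[c] = np.nanpercentile(col, qs).tolist()
        if c not in edges:
            continue
        binned = np.searchsorted(np.asarray(edges[c]), col, side="left") + 1.0
        binned[np.isnan(col)] = np.nan
        n_distinct = pd.Series(binned).dropna().nunique()
        if n_distinct < cfg.n_bins and fitting:
            warnings.warn(f"column {c!r}: only {n_distinct} distinct bins after quartile binning")
        out.frame[c] = binned
        out.meta[c] = ColumnMeta(c, out.meta[c].role, "ordinal", list(range(1, cfg.n_bins + 1)))
    return out, edges


# ---------------------------------------------------------------------------
# ordinal encoding with a missing class
# ---------------------------------------------------------------------------

def encode_and_impute(data: SurveyDataset, cfg: PrepConfig, maps: dict | None = None):
    """Map every modeled column to consecutive positive integer codes.

    Codes start at 1 in declared (or sorted observed) level order, so code 0
    is always free for the missing class — a raw value of 0 is shifted up
    rather than colliding. Levels unseen at fit time map to the missing
    code with a warning. Returns ``(encoded, maps)``.
    """
    out = data.copy()
    fitting = maps is None
    maps = {} if fitting else maps
    for c in _modeled_columns(out):
        col = out.frame[c]
        if fitting:
            declared = out.meta[c].levels
            observed = sorted(col.dropna().unique().tolist())
            if declared is not None and all(v in declared for v in observed):
                order = [v for v in declared if v in observed]
            else:
                order = observed
            maps[c] = {lvl: i + 1 for i, lvl in enumerate(order)}
        mapping = maps[c]
        coded = col.map(mapping)
        unseen = coded.isna() & col.notna()
        if unseen.any():
            warnings.warn(f"column {c!r}: {int(unseen.sum())} values unseen at fit time mapped to missing code")
        coded = coded.fillna(cfg.missing_code).astype(int)
        out.frame[c] = coded
        out.meta[c] = ColumnMeta(c, out.meta[c].role, "ordinal", sorted(set(mapping.values()) | {cfg.missing_code}))
    return out, maps


def decode(data: SurveyDataset, maps: dict) -> SurveyDataset:
    """Inverse of :func:`encode_and_impute` for non-missing codes."""
    out = data.copy()
    for c, mapping in maps.items():
        if c not in out.frame.columns:
            continue
        inverse = {code: lvl for lvl, code in mapping.items()}
        out.frame[c] = out.frame[c].map(inverse)
    return out


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(train: SurveyDataset, test: SurveyDataset | None = None):
    """z-score the modeled columns using training statistics only.

    Returns ``(train_z, test_z, stats)`` where the frames contain only the
    modeled (feature) columns. Used by the classifier path; structure
    learning keeps the discrete codes.
    """
    cols = _modeled_columns(train)
    x = train.frame[cols].astype(float)
    mean = x.mean()
    sd = x.std(ddof=0)
    if (sd <= 0).any():
        raise ValueError(f"zero variance in columns {list(sd[sd <= 0].index)}")
    stats = StandardizationStats(mean=mean, sd=sd)
    train_z = (x - mean) / sd
    test_z = None
    if test is not None:
        test_z = (test.frame[cols].astype(float) - mean) / sd
    return train_z, test_z, stats


# ---------------------------------------------------------------------------
# end-to-end preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedData:
    train: SurveyDataset
    test: SurveyDataset
    train_z: pd.DataFrame
    test_z: pd.DataFrame
    stats: StandardizationStats
    drop_report: dict
    bin_edges: dict
    encoding_maps: dict
    cfg: PrepConfig = field(default_factory=PrepConfig)

    @property
    def feature_names(self) -> list[str]:
        return list(self.train_z.columns)

    def discrete_train(self, outcome_name: str = "DS") -> pd.DataFrame:
        """Encoded training codes plus the outcome column, for structure learning."""
        df = self.train.frame[self.feature_names].copy()
        df[outcome_name] = self.train.outcome.to_numpy()
        return df


def prepare(data: SurveyDataset, cfg: PrepConfig | None = None) -> PreparedData:
    """Run the full preparation pipeline on a raw survey dataset.

    Split first, then per-partition outcome construction; all filters,
    quartile edges, encoding maps and standardization statistics are fitted
    on the training partition and reused on the test partition.
    """
    cfg = cfg or PrepConfig()
    cfg.validate()
    train_raw, test_raw = split_train_test(data, cfg)
    train = build_outcome(train_raw, cfg)
    test = build_outcome(test_raw, cfg)

    train, report = filter_columns_and_rows(train, cfg)
    drop_cols = [d["name"] for d in report["columns"]]
    test = test.drop_columns(drop_cols)
    modeled_test = _modeled_columns(test)
    if modeled_test:
        row_frac = test.frame[modeled_test].isna().mean(axis=1)
        test = test.select_rows(row_frac <= cfg.missing_respondent_threshold)

    train, edges = bin_high_cardinality(train, cfg)
    test, _ = bin_high_cardinality(test, cfg, edges=edges)
    train, maps = encode_and_impute(train, cfg)
    test, _ = encode_and_impute(test, cfg, maps=maps)
    train_z, test_z, stats = standardize(train, test)
    return PreparedData(
        train=train,
        test=test,
        train_z=train_z,
        test_z=test_z,
        stats=stats,
        drop_report=report,
        bin_edges=edges,
        encoding_maps=maps,
        cfg=cfg,
    )
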