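"""Survey dataset container: a respondent × item table plus a data dictionary.

Every column carries a *role* (how the pipeline treats it) and a declared
*type*. Missing values are represented as NaN in memory and as empty cells
in CSV. The binary depressive-symptomatology outcome, once constructed from
the PHQ-9 items, lives alongside the table rather than inside it so that
feature matrices never accidentally contain the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: column roles understood by the pipeline
ROLES = ("phq9_item", "depression_related", "feature", "id")
#: declared column types
TYPES = ("binary", "ordinal", "numeric")


@dataclass
class ColumnMeta:
    """Data-dictionary entry for one column."""

    name: str
    role: str
    dtype: str
    levels: list | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for column {self.name!r}")
        if self.dtype not in TYPES:
            raise ValueError(f"unknown type {self.dtype!r} for column {self.name!r}")


@dataclass
class SurveyDataset:
    """A survey table with per-column metadata and an optional binary outcome.

    Parameters
    ----------
    frame
        Respondent × column table. NaN marks missing answers.
    meta
        One :class:`ColumnMeta` per column of ``frame``.
    outcome
        Optional 0/1 series aligned with ``frame`` (depressive
        symptomatology, PHQ-9 sum ≥ cutoff).
    """

    frame: pd.DataFrame
    meta: dict[str, ColumnMeta] = field(default_factory=dict)
    outcome: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.frame.columns if c not in self.meta]
        if missing:
            raise ValueError(f"columns without metadata: {missing}")
        if self.outcome is not None:
            vals = self.outcome.dropna().unique()
            if not set(vals) <= {0, 1}:
                raise ValueError("outcome must be binary 0/1")

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.frame.columns if self.meta[c].role in roles]

    @property
    def feature_columns(self) -> list[str]:
        return self.columns_with_role("feature")

    @property
    def phq9_columns(self) -> list[str]:
        return self.columns_with_role("phq9_item")

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(
            self.frame.copy(),
            {k: ColumnMeta(v.name, v.role, v.dtype, None if v.levels is None else list(v.levels)) for k, v in self.meta.items()},
            None if self.outcome is None else self.outcome.copy(),
        )

    def select_rows(self, mask_or_index) -> "SurveyDataset":
        frame = self.frame.loc[mask_or_index]
        outcome = None if self.outcome is None else self.outcome.loc[frame.index]
        return SurveyDataset(frame, dict(self.meta), outcome)

    def drop_columns(self, cols) -> "SurveyDataset":
        cols = [c for c in cols if c in self.frame.columns]
        frame = self.frame.drop(columns=cols)
        meta = {k: v for k, v in self.meta.items() if k not in cols}
        return SurveyDataset(frame, meta, self.outcome)

    # -- I/O ---------------------------------------------------------------
    def write(self, out_dir: str | Path, stem: str = "survey") -> None:
        """Write ``<stem>.csv`` (empty cell = missing) and ``<stem>.dict.yaml``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(out_dir / f"{stem}.csv", index=False)
        dictionary = [
            {
                "name": m.name,
                "role": m.role,
                "type": m.dtype,
                "levels": m.levels,
            }
            for m in self.meta.values()
        ]
        with open(out_dir / f"{stem}.dict.yaml", "w") as fh:
            yaml.safe_dump(dictionary, fh, sort_keys=False)
        if self.outcome is not None:
            self.outcome.to_frame("outcome").to_csv(out_dir / f"{stem}.outcome.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path, stem: str = "survey") -> "SurveyDataset":
        in_dir = Path(in_dir)
        frame = pd.read_csv(in_dir / f"{stem}.csv")
        with open(in_dir / f"{stem}.dict.yaml") as fh:
            dictionary = yaml.safe_load(fh)
        meta = {d["name"]: ColumnMeta(d["name"], d["role"], d["type"], d.get("levels")) for d in dictionary}
        outcome_path = in_dir / f"{stem}.outcome.csv"
        outcome = None
        if outcome_path.exists():
            outcome = pd.read_csv(outcome_path)["outcome"]
            outcome.index = frame.index
        return cls(frame, meta, outcome)


def frames_equal(a: SurveyDataset, b: SurveyDataset) -> bool:
    """Field-by-field equality, treating NaN == NaN."""
    if list(a.frame.columns) != list(b.frame.columns) or len(a.frame) != len(b.frame):
        return False
    for c in a.frame.columns:
        av, bv = a.frame[c].to_numpy(), b.frame[c].to_numpy()
        if not ((av == bv) | (pd.isna(av) & pd.isna(bv))).all():
            return False
    return json.dumps({k: vars(v) for k, v in a.meta.items()}, default=str) == json.dumps(
        {k: vars(v) for k, v in b.meta.items()}, default=str
    )
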