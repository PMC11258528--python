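"""Bayesian CPD estimation and scenario-probability queries.

Given the learned directed structure, each node's conditional probability
distribution is the posterior mean under a uniform Dirichlet prior with
equivalent sample size ``ess``: P(child=k | config) = (n_k + ess/K) /
(n_config + ess). The outcome node's table answers the scenario questions
the screening study asks — e.g. how much more probable depressive
symptomatology is for the all-risk-factor configuration than for the
all-protective one.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import BNGraph


@dataclass
class CpdTable:
    """P(child | parent configuration) with Dirichlet smoothing.

    ``table`` has one row per parent configuration (row-major over
    ``parent_levels``, first parent slowest) and one column per child state.
    """

    child: str
    parents: list[str]
    parent_levels: list[list]
    child_levels: list
    table: np.ndarray
    ess: float

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("CPD rows must sum to 1")
        if self.ess > 0 and self.table.shape[1] > 1 and ((self.table <= 0) | (self.table >= 1)).any():
            raise ValueError("with ess > 0 all probabilities must be in (0,1)")

    def config_index(self, assignment: dict) -> int:
        missing = [p for p in self.parents if p not in assignment]
        if missing:
            raise KeyError(f"assignment missing parents: {missing}")
        idx = 0
        for p, levels in zip(self.parents, self.parent_levels):
            if assignment[p] not in levels:
                raise ValueError(f"{assignment[p]!r} is not a level of {p!r}")
            idx = idx * len(levels) + levels.index(assignment[p])
        return idx

    def row(self, assignment: dict) -> np.ndarray:
        return self.table[self.config_index(assignment)]

    def to_dict(self) -> dict:
        return {
            "child": self.child,
            "parents": self.parents,
            "parent_levels": [[_py(v) for v in lv] for lv in self.parent_levels],
            "child_levels": [_py(v) for v in self.child_levels],
            "table": self.table.tolist(),
            "ess": self.ess,
        }


def _py(v):
    return v.item() if isinstance(v, np.generic) else v


def fit_cpd_bayes(graph: BNGraph, data: pd.DataFrame, ess: float = 1.0) -> dict[str, CpdTable]:
    """Posterior-mean CPDs for every node of ``graph`` from discrete data.

    Unobserved parent configurations fall back to the uniform prior row;
    in the ess→0 limit the estimate is the maximum-likelihood frequency.
    """
    missing = [v for v in graph.nodes if v not in data.columns]
    if missing:
        raise KeyError(f"nodes absent from data: {missing}")
    if ess < 0:
        raise ValueError("ess must be ≥ 0")
    out: dict[str, CpdTable] = {}
    for node in graph.nodes:
        parents = sorted(graph.parents(node))
        child_levels = sorted(pd.unique(data[node]).tolist())
        k = len(child_levels)
        parent_levels = [sorted(pd.unique(data[p]).tolist()) for p in parents]
        cards = [len(lv) for lv in parent_levels]
        n_cfg = int(np.prod(cards)) if cards else 1
        child_idx = pd.Categorical(data[node], categories=child_levels).codes.astype(np.int64)
        if parents:
            cfg_idx = np.zeros(len(data), dtype=np.int64)
            for p, lv in zip(parents, parent_levels):
                cfg_idx = cfg_idx * len(lv) + pd.Categorical(data[p], categories=lv).codes
        else:
            cfg_idx = np.zeros(len(data), dtype=np.int64)
        counts = np.bincount(cfg_idx * k + child_idx, minlength=n_cfg * k).reshape(n_cfg, k).astype(float)
        if ess > 0:
            table = (counts + ess / k) / (counts.sum(axis=1, keepdims=True) + ess)
        else:
            tot = counts.sum(axis=1, keepdims=True)
            uniform = np.full((n_cfg, k), 1.0 / k)
            with np.errstate(invalid="ignore", divide="ignore"):
                table = np.where(tot > 0, counts / np.maximum(tot, 1), uniform)
        out[node] = CpdTable(node, parents, parent_levels, child_levels, table, ess)
    return out


def scenario_probability(cpd: CpdTable, assignment: dict, positive_state=None) -> float:
    """P(child = positive state | parent assignment) from a fitted table."""
    row = cpd.row(assignment)
    state = cpd.child_levels[-1] if positive_state is None else positive_state
    return float(row[cpd.child_levels.index(state)])


def scenario_report(cpds: dict[str, CpdTable], outcome: str, top_k: int | None = None, positive_state=None) -> pd.DataFrame:
    """All parent configurations of the outcome ranked by P(outcome positive).

    The frame carries one column per parent plus ``p_positive``; its
    ``attrs['contrast_ratio']`` holds max/min — the discriminatory-power
    summary the scenario tables highlight.
    """
    cpd = cpds[outcome]
    state = cpd.child_levels[-1] if positive_state is None else positive_state
    col = cpd.child_levels.index(state)
    rows = []
    for cfg in itertools.product(*[range(len(lv)) for lv in cpd.parent_levels]) if cpd.parents else [()]:
        idx = 0
        for j, lv in zip(cfg, cpd.parent_levels):
            idx = idx * len(lv) + j
        rec = {p: lv[j] for p, lv, j in zip(cpd.parents, cpd.parent_levels, cfg)}
        rec["p_positive"] = float(cpd.table[idx, col])
        rows.append(rec)
    frame = pd.DataFrame(rows).sort_values("p_positive", ascending=False, kind="stable").reset_index(drop=True)
    contrast = float(frame["p_positive"].max() / frame["p_positive"].min())
    if top_k is not None:
        frame = frame.head(top_k)
    frame.attrs["contrast_ratio"] = contrast
    return frame


def save_cpds(cpds: dict[str, CpdTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in cpds.items()}, fh, indent=1)


def load_cpds(path: str | Path) -> dict[str, CpdTable]:
    with open(path) as fh:
        raw = json.load(fh)
    return {
        k: CpdTable(d["child"], d["parents"], d["parent_levels"], d["child_levels"], np.array(d["table"]), d["ess"])
        for k, d in raw.items()
    }
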