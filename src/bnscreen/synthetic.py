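"""Synthetic survey generator with a known ground-truth discrete network.

The generator emulates the kind of general-health / sociodemographic survey
used for depression prescreening: a binary latent depressive-symptomatology
(DS) state sits inside a known directed acyclic graph, with a designated
Markov blanket (parents, children, spouses), and is *observed* only through
nine PHQ-9-style items (each scored 0–3) whose sum defines the recorded
outcome at the usual cut-off of ≥10. Nuisance columns (constants,
high-cardinality numerics, depression-related proxies) exercise the
data-preparation filters.

Because the generating network is known exactly, every downstream stage has
an oracle: the observed-outcome conditional probability table and the
Bayes-optimal AUC are computed in closed form by enumeration here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, softmax

from .dataset import ColumnMeta, SurveyDataset

# PHQ-9 item-score distributions given the latent DS state. Items are drawn
# i.i.d. given DS; the instrument is treated as highly (not perfectly)
# reliable, so the recorded sum≥10 outcome is a mildly noisy proxy of DS.
DEFAULT_PHQ9_EMISSION = {
    0: np.array([0.82, 0.13, 0.04, 0.01]),
    1: np.array([0.04, 0.12, 0.30, 0.54]),
}
PHQ9_CUTOFF = 10


@dataclass
class GroundTruthSpec:
    """Declarative description of the planted network.

    ``feature_cardinalities`` covers every modeled (non-nuisance) feature;
    the Markov-blanket role lists must be disjoint subsets of its keys.
    ``effect_size`` is a log-odds shift: how strongly a one-unit (rescaled)
    change in a blanket variable moves P(DS), from ~0 (null) to
    near-deterministic (≥4).
    """

    feature_cardinalities: dict[str, int]
    outcome_name: str = "DS"
    mb_parents: list[str] = field(default_factory=list)
    mb_children: list[str] = field(default_factory=list)
    mb_spouses: list[str] = field(default_factory=list)
    n_nuisance_constant: int = 0
    n_numeric_highcard: int = 0
    n_depression_related: int = 0
    effect_size: float = 2.0
    prevalence: float = 0.10
    seed: int = 0

    @property
    def n_features(self) -> int:
        return len(self.feature_cardinalities)

    def validate(self) -> None:
        sets = [set(self.mb_parents), set(self.mb_children), set(self.mb_spouses)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError(f"MB role sets overlap: {sets[i] & sets[j]}")
        blanket = sets[0] | sets[1] | sets[2]
        if self.outcome_name in blanket or self.outcome_name in self.feature_cardinalities:
            raise ValueError("outcome must not appear among the features or its own blanket")
        unknown = blanket - set(self.feature_cardinalities)
        if unknown:
            raise ValueError(f"MB members missing from feature_cardinalities: {unknown}")
        bad = {f: k for f, k in self.feature_cardinalities.items() if k < 2}
        if bad:
            raise ValueError(f"modeled features need cardinality ≥2: {bad}")
        if self.mb_spouses and not self.mb_children:
            raise ValueError("spouses require at least one child to co-parent")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")


@dataclass
class GroundTruthNetwork:
    """Planted network: DAG, per-node CPDs, and the PHQ-9 emission model."""

    spec: GroundTruthSpec
    graph: nx.DiGraph
    #: node -> {"parents": [...], "cards": [...], "table": (n_configs, K) array}
    cpds: dict
    phq9_emission: dict

    # -- exact quantities --------------------------------------------------
    def phq9_positive_prob(self, ds_state: int, cutoff: int = PHQ9_CUTOFF) -> float:
        """P(sum of 9 items ≥ cutoff | DS state), by exact convolution."""
        dist = np.array([1.0])
        item = np.asarray(self.phq9_emission[ds_state])
        for _ in range(9):
            dist = np.convolve(dist, item)
        return float(dist[cutoff:].sum())

    def latent_outcome_cpd(self) -> np.ndarray:
        """P(DS=1 | parent config) for every parent configuration."""
        return self.cpds[self.spec.outcome_name]["table"][:, 1].copy()

    def observed_outcome_cpd(self) -> np.ndarray:
        """P(recorded PHQ-9 outcome = 1 | parent config).

        The recorded outcome mixes the latent CPD with the emission noise:
        P(obs|pa) = P(obs|DS=0)(1-p) + P(obs|DS=1)p with p = P(DS=1|pa).
        This is the ground truth for what parameter learning estimates from
        the sampled data.
        """
        p = self.latent_outcome_cpd()
        e0 = self.phq9_positive_prob(0)
        e1 = self.phq9_positive_prob(1)
        return e0 * (1.0 - p) + e1 * p

    def outcome_parent_configs(self) -> list[tuple]:
        cards = self.cpds[self.spec.outcome_name]["cards"]
        return list(itertools.product(*[range(k) for k in cards]))

    def markov_blanket(self) -> set[str]:
        s = self.spec
        return set(s.mb_parents) | set(s.mb_children) | set(s.mb_spouses)

    def bayes_auc(self) -> float:
        """Exact AUC of the Bayes-optimal score P(obs=1 | features).

        Only the Markov blanket carries information about the outcome, so
        the joint over (blanket config, observed outcome) is enumerated in
        closed form and the AUC computed as the weighted concordance
        probability with ties counted 1/2.
        """
        s = self.spec
        e = [self.phq9_positive_prob(0), self.phq9_positive_prob(1)]
        pa, sp, ch = list(s.mb_parents), list(s.mb_spouses), list(s.mb_children)
        nodes = pa + sp + ch
        cards = [s.feature_cardinalities[v] for v in nodes]
        out_cpd = self.cpds[s.outcome_name]
        p1_mass, p0_mass = [], []
        for cfg in itertools.product(*[range(k) for k in cards]):
            a = dict(zip(nodes, cfg))
            w_roots = 1.0
            for v in pa + sp:
                w_roots *= self.cpds[v]["table"][0, a[v]]
            pa_idx = (
                np.ravel_multi_index([a[v] for v in pa], out_cpd["cards"])
                if pa
                else 0
            )
            joint = np.zeros(2)  # over DS
            for ds in (0, 1):
                w = w_roots * out_cpd["table"][pa_idx, ds]
                for c in ch:
                    cpd = self.cpds[c]
                    vals = [ds if p == s.outcome_name else a[p] for p in cpd["parents"]]
                    idx = np.ravel_multi_index(vals, cpd["cards"]) if cpd["parents"] else 0
                    w *= cpd["table"][idx, a[c]]
                joint[ds] = w
            p1 = joint[0] * e[0] + joint[1] * e[1]
            p0 = joint[0] * (1 - e[0]) + joint[1] * (1 - e[1])
            p1_mass.append(p1)
            p0_mass.append(p0)
        p1_mass = np.array(p1_mass) / np.sum(p1_mass)
        p0_mass = np.array(p0_mass) / np.sum(p0_mass)
        score = np.where(
            p1_mass + p0_mass > 0,
            p1_mass / np.maximum(p1_mass + p0_mass, 1e-300),
            0.5,
        )
        order = np.argsort(score, kind="stable")
        s1, s0, sc = p1_mass[order], p0_mass[order], score[order]
        # group ties, accumulate P(score_pos > score_neg) + 1/2 P(equal)
        auc = 0.0
        cum0 = 0.0
        i = 0
        while i < len(sc):
            j = i
            while j < len(sc) and sc[j] == sc[i]:
                j += 1
            g1, g0 = s1[i:j].sum(), s0[i:j].sum()
            auc += g1 * cum0 + 0.5 * g1 * g0
            cum0 += g0
            i = j
        return float(auc)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _scaled(level: np.ndarray | int, card: int) -> np.ndarray | float:
    """Map a level in 0..card-1 to [-1, 1]."""
    if card == 1:
        return 0.0
    return 2.0 * (np.asarray(level, dtype=float) / (card - 1)) - 1.0


def make_ground_truth_network(spec: GroundTruthSpec) -> GroundTruthNetwork:
    """Build the planted network implied by ``spec``.

    Roots (parents, spouses, and any feature outside the blanket) get
    mildly random categorical marginals. The outcome CPD is logit-additive
    in the rescaled parent levels with slope ``effect_size``; its intercept
    is solved so the marginal latent prevalence equals ``spec.prevalence``.
    Children are softmax-monotone in the DS state and their co-parent
    spouses (spouses assigned to children round-robin). Everything is
    reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec
    g = nx.DiGraph()
    g.add_nodes_from(list(s.feature_cardinalities) + [s.outcome_name])

    cpds: dict = {}
    blanket = set(s.mb_parents) | set(s.mb_children) | set(s.mb_spouses)
    roots = [f for f in s.feature_cardinalities if f not in set(s.mb_children)]
    for f in sorted(roots):
        k = s.feature_cardinalities[f]
        marg = rng.dirichlet(np.full(k, 5.0))
        cpds[f] = {"parents": [], "cards": [], "table": marg[None, :]}

    # outcome | parents: logit-additive, intercept calibrated to prevalence
    pa = list(s.mb_parents)
    pa_cards = [s.feature_cardinalities[p] for p in pa]
    for p in pa:
        g.add_edge(p, s.outcome_name)
    configs = list(itertools.product(*[range(k) for k in pa_cards])) or [()]
    shifts = np.array(
        [sum(s.effect_size * _scaled(lv, k) for lv, k in zip(cfg, pa_cards)) for cfg in configs]
    )
    weights = np.array(
        [np.prod([cpds[p]["table"][0, lv] for p, lv in zip(pa, cfg)]) if pa else 1.0 for cfg in configs]
    )

    def _prev(base: float) -> float:
        return float(np.sum(weights * expit(base + shifts))) - s.prevalence

    base = brentq(_prev, -40.0, 40.0)
    p1 = expit(base + shifts)
    cpds[s.outcome_name] = {
        "parents": pa,
        "cards": pa_cards,
        "table": np.column_stack([1.0 - p1, p1]),
    }

    # children | DS (+ assigned spouses): softmax monotone in the drive
    spouse_of = {c: [] for c in s.mb_children}
    for i, sp in enumerate(sorted(s.mb_spouses)):
        spouse_of[sorted(s.mb_children)[i % len(s.mb_children)]].append(sp)
    for c in sorted(s.mb_children):
        g.add_edge(s.outcome_name, c)
        for sp in spouse_of[c]:
            g.add_edge(sp, c)
        parents = [s.outcome_name] + spouse_of[c]
        cards = [2] + [s.feature_cardinalities[sp] for sp in spouse_of[c]]
        k = s.feature_cardinalities[c]
        u = rng.normal(0.0, 0.3, size=k)
        rows = []
        for cfg in itertools.product(*[range(r) for r in cards]):
            drive = _scaled(cfg[0], 2) + sum(
                _scaled(lv, s.feature_cardinalities[sp]) for sp, lv in zip(spouse_of[c], cfg[1:])
            )
            logits = u + s.effect_size * _scaled(np.arange(k), k) * drive
            rows.append(softmax(logits))
        cpds[c] = {"parents": parents, "cards": cards, "table": np.array(rows)}

    net = GroundTruthNetwork(spec=s, graph=g, cpds=cpds, phq9_emission=dict(DEFAULT_PHQ9_EMISSION))
    if not nx.is_directed_acyclic_graph(g):  # defensive; disjointness implies acyclic
        raise ValueError("spec implies a cyclic graph")
    if net.phq9_positive_prob(1) <= net.phq9_positive_prob(0):
        raise ValueError("PHQ-9 emission must separate the DS states")
    _ = blanket
    return net


def example_spec(seed: int = 0, effect_size: float = 3.0, prevalence: float = 0.10) -> GroundTruthSpec:
    """The canonical 10-node study configuration used in the docs and tests.

    Two parents, two children, two spouses (blanket of six) and three
    independent nuisance features, with health-survey-flavoured names.
    """
    return GroundTruthSpec(
        feature_cardinalities={
            "balance_problem": 2,
            "age_felt": 3,
            "sleep_meds": 2,
            "usual_activities": 2,
            "chest_pain": 2,
            "back_pain": 2,
            "income_band": 3,
            "exercise": 2,
            "smoker": 2,
        },
        outcome_name="DS",
        mb_parents=["balance_problem", "age_felt"],
        mb_children=["sleep_meds", "usual_activities"],
        mb_spouses=["chest_pain", "back_pain"],
        n_nuisance_constant=1,
        n_numeric_highcard=1,
        n_depression_related=1,
        effect_size=effect_size,
        prevalence=prevalence,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_rows(table: np.ndarray, cfg_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one categorical value per row from ``table[cfg_idx[i]]``."""
    probs = table[cfg_idx]
    u = rng.random(len(cfg_idx))
    return (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)


def sample_survey(network: GroundTruthNetwork, n: int, seed: int) -> SurveyDataset:
    """Ancestral sampling of ``n`` respondents in topological order.

    The latent DS state is stored (role ``depression_related``, so the
    preparation stage drops it) alongside the nine PHQ-9 item columns from
    which the recorded outcome is later derived. The configured nuisance
    columns are appended: an ``age`` column (integer 18–90, >30 distinct
    levels) plus further high-cardinality numerics, constant columns, and
    noisy depression-related proxies of DS.
    """
    if n < 0:
        raise ValueError("n must be ≥ 0")
    s = network.spec
    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(network.graph))
    values: dict[str, np.ndarray] = {}
    for node in order:
        cpd = network.cpds[node]
        if cpd["parents"]:
            idx = np.ravel_multi_index([values[p] for p in cpd["parents"]], cpd["cards"]) if n else np.zeros(0, dtype=int)
        else:
            idx = np.zeros(n, dtype=int)
        values[node] = _sample_rows(cpd["table"], idx, rng)

    ds = values[s.outcome_name]
    frame = {"respondent_id": np.arange(n)}
    meta = {"respondent_id": ColumnMeta("respondent_id", "id", "numeric")}
    for f in s.feature_cardinalities:
        k = s.feature_cardinalities[f]
        frame[f] = values[f]
        meta[f] = ColumnMeta(f, "feature", "binary" if k == 2 else "ordinal", list(range(k)))
    for j in range(s.n_numeric_highcard):
        name = "age" if j == 0 else f"num_hc_{j}"
        col = rng.integers(18, 91, size=n) if j == 0 else np.round(rng.normal(50, 15, size=n), 2)
        frame[name] = col
        meta[name] = ColumnMeta(name, "feature", "numeric")
    for j in range(s.n_nuisance_constant):
        name = f"const_{j + 1}"
        frame[name] = np.ones(n, dtype=int)
        meta[name] = ColumnMeta(name, "feature", "ordinal", [1])
    for j in range(s.n_depression_related):
        name = f"depression_proxy_{j + 1}"
        flip = rng.random(n) < 0.1
        frame[name] = np.where(flip, 1 - ds, ds)
        meta[name] = ColumnMeta(name, "depression_related", "binary", [0, 1])
    frame["ds_latent"] = ds
    meta["ds_latent"] = ColumnMeta("ds_latent", "depression_related", "binary", [0, 1])
    item_probs = np.stack([network.phq9_emission[0], network.phq9_emission[1]])
    for j in range(1, 10):
        name = f"phq9_{j}"
        frame[name] = _sample_rows(item_probs, ds, rng)
        meta[name] = ColumnMeta(name, "phq9_item", "ordinal", [0, 1, 2, 3])
    df = pd.DataFrame(frame).astype(float)
    df["respondent_id"] = df["respondent_id"].astype(int)
    return SurveyDataset(df, meta)


def inject_missingness(
    data: SurveyDataset,
    feature_rates: dict[str, float] | None = None,
    respondent_rate: float = 0.0,
    seed: int = 0,
    respondent_cell_rate: float = 0.5,
) -> SurveyDataset:
    """Set entries to missing completely at random.

    ``feature_rates`` masks each named column's cells independently at the
    given per-column rate; ``respondent_rate`` selects that fraction of
    respondents and masks each of their non-id cells with probability
    ``respondent_cell_rate``, producing the heavily incomplete respondents
    the >20 %-missing row filter is meant to catch.
    """
    feature_rates = feature_rates or {}
    for name, r in feature_rates.items():
        if not 0 <= r <= 1:
            raise ValueError(f"rate for {name!r} outside [0,1]")
        if name not in data.frame.columns:
            raise ValueError(f"unknown column {name!r}")
    if not 0 <= respondent_rate <= 1:
        raise ValueError("respondent_rate outside [0,1]")
    rng = np.random.default_rng(seed)
    out = data.copy()
    n = out.n
    for name, r in feature_rates.items():
        mask = rng.random(n) < r
        col = out.frame[name].astype(float).to_numpy()
        col[mask] = np.nan
        out.frame[name] = col
    if respondent_rate > 0:
        rows = rng.random(n) < respondent_rate
        maskable = [c for c in out.frame.columns if out.meta[c].role != "id"]
        cells = rng.random((n, len(maskable))) < respondent_cell_rate
        for j, c in enumerate(maskable):
            mask = rows & cells[:, j]
            col = out.frame[c].astype(float).to_numpy()
            col[mask] = np.nan
            out.frame[c] = col
    return out
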