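"""End-to-end study replica: synthesize → prepare → learn → fit → screen.

A single :class:`RunConfig` drives the whole pipeline under one global
seed; per-stage seeds are derived deterministically from it. Defaults are
the study's own settings (70/30 split, >20 % missing filters, >30-level →
4-bin quartiles, 1000 bootstrap replicates, strength ≥ 50 %, P ≥ .05 edge
pruning, 5-fold CV, Youden thresholding); any override is recorded as a
deviation in the run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, parameters, prep, screening, structure, synthetic

PAPER_DEFAULTS = {
    "train_fraction": 0.70,
    "missing_feature_threshold": 0.20,
    "missing_respondent_threshold": 0.20,
    "highcard_level_threshold": 30,
    "n_bins": 4,
    "bootstrap_B": 1000,
    "strength_threshold": 0.5,
    "alpha": 0.05,
    "cv_folds": 5,
}


@dataclass
class RunConfig:
    seed: int = 0
    n_samples: int = 20000
    spec: synthetic.GroundTruthSpec | None = None
    prep: prep.PrepConfig = field(default_factory=prep.PrepConfig)
    bootstrap_B: int = 1000
    strength_threshold: float = 0.5
    alpha: float = 0.05
    ess: float = 1.0
    feature_set: str = "both"  # mb | all_path | both
    search_iters: int = 15
    cv_folds: int = 5
    respondent_missing_rate: float = 0.0
    feature_missing_rates: dict = field(default_factory=dict)
    out_dir: str | None = None

    def stage_seed(self, stage: int) -> int:
        state = np.random.SeedSequence([self.seed, stage]).generate_state(1)[0]
        return int(state) & 0x7FFFFFFF


def validate_config(raw: dict | RunConfig):
    """Normalize a config mapping, listing errors and deviations from defaults.

    Returns ``(RunConfig, deviations)``; raises ValueError listing every
    contradiction found rather than silently fixing any.
    """
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        raw = dict(raw or {})
        prep_over = raw.pop("prep", {})
        spec_over = raw.pop("spec", None)
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(**raw)
        cfg.prep = prep.PrepConfig(**prep_over) if isinstance(prep_over, dict) else prep_over
        if isinstance(spec_over, dict):
            cfg.spec = synthetic.GroundTruthSpec(**spec_over)
        elif spec_over is not None:
            cfg.spec = spec_over
    errors = []
    try:
        cfg.prep.validate()
    except ValueError as e:
        errors.append(str(e))
    if cfg.feature_set not in ("mb", "all_path", "both"):
        errors.append(f"feature_set must be mb/all_path/both, got {cfg.feature_set!r}")
    if cfg.bootstrap_B < 1:
        errors.append("bootstrap_B must be ≥ 1")
    if not 0 < cfg.strength_threshold <= 1:
        errors.append("strength_threshold must be in (0,1]")
    if errors:
        raise ValueError("; ".join(errors))
    if cfg.spec is None:
        cfg.spec = synthetic.example_spec(seed=cfg.stage_seed(0))
    deviations = []
    current = {
        "train_fraction": cfg.prep.train_fraction,
        "missing_feature_threshold": cfg.prep.missing_feature_threshold,
        "missing_respondent_threshold": cfg.prep.missing_respondent_threshold,
        "highcard_level_threshold": cfg.prep.highcard_level_threshold,
        "n_bins": cfg.prep.n_bins,
        "bootstrap_B": cfg.bootstrap_B,
        "strength_threshold": cfg.strength_threshold,
        "alpha": cfg.alpha,
        "cv_folds": cfg.cv_folds,
    }
    for key, default in PAPER_DEFAULTS.items():
        if current[key] != default:
            deviations.append(f"{key}={current[key]} (default {default})")
    return cfg, deviations


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig | dict) -> dict:
    """Execute every stage in order and return the consolidated report.

    When ``out_dir`` is set, stage artifacts (dataset, edge-confidence
    table, CPDs, models, curves, the JSON/Markdown report) are written
    there; the expensive bootstrap stage is reloaded from disk on reruns
    with an identical configuration.
    """
    cfg, deviations = validate_config(cfg)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": _config_hash(cfg), "deviations": deviations, "stages": {}}

    # stage 1 — synthesize
    network = synthetic.make_ground_truth_network(cfg.spec)
    data = synthetic.sample_survey(network, cfg.n_samples, seed=cfg.stage_seed(1))
    if cfg.respondent_missing_rate or cfg.feature_missing_rates:
        data = synthetic.inject_missingness(
            data, cfg.feature_missing_rates, cfg.respondent_missing_rate, seed=cfg.stage_seed(2)
        )
    if out:
        data.write(out, stem="survey")
    report["stages"]["synthesize"] = {"n": data.n, "planted_mb": sorted(network.markov_blanket())}

    # stage 2 — prepare
    cfg.prep.seed = cfg.stage_seed(3)
    prepped = prep.prepare(data, cfg.prep)
    report["stages"]["prepare"] = {
        "drop_report": prepped.drop_report,
        "n_train": prepped.train.n,
        "n_test": prepped.test.n,
        "prevalence_train": float(prepped.train.outcome.mean()),
    }

    # stage 3 — structure learning with bootstrap confidence
    disc = prepped.discrete_train("DS")
    conf = None
    conf_path = out / "edge_confidence.csv" if out else None
    meta_path = out / "stage_meta.json" if out else None
    if conf_path and conf_path.exists() and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("config_hash") == report["config_hash"]:
            cached = pd.read_csv(conf_path)
            conf = structure.EdgeConfidence(nodes=list(disc.columns), n_boot=cfg.bootstrap_B)
            for _, r in cached.iterrows():
                e = frozenset((r["from"], r["to"]))
                present = int(round(r["strength"] * cfg.bootstrap_B))
                conf.presence[e] = present
                conf.orientation[(r["from"], r["to"])] = r["direction"] * present
                conf.orientation[(r["to"], r["from"])] = (1 - r["direction"]) * present
    if conf is None:
        conf = structure.bootstrap_confidence(disc, B=cfg.bootstrap_B, alpha=cfg.alpha, seed=cfg.stage_seed(4))
        if conf_path:
            conf.to_frame().to_csv(conf_path, index=False)
            meta_path.write_text(json.dumps({"config_hash": report["config_hash"]}))
    graph, notes = structure.average_network(conf, cfg.strength_threshold)
    pruned = structure.prune_by_independence(graph, disc, alpha=cfg.alpha)
    report["stages"]["structure"] = {
        "edges": sorted([list(e) for e in pruned.directed]),
        "notes": notes,
        "n_pruned_edges": len(graph.skeleton_edges()) - len(pruned.skeleton_edges()),
    }

    # stage 4 — feature sets
    mb = structure.markov_blanket_of(pruned, "DS")
    apf = structure.all_path_features(pruned, "DS")
    scenarios = {}
    if cfg.feature_set in ("mb", "both"):
        scenarios["markov_blanket"] = sorted(mb.all())
    if cfg.feature_set in ("all_path", "both"):
        scenarios["all_path_features"] = sorted(apf)
    report["stages"]["feature_sets"] = {k: v for k, v in scenarios.items()}

    # stage 5 — CPDs and scenario probabilities for the outcome
    cpds = parameters.fit_cpd_bayes(pruned, disc, ess=cfg.ess)
    if cpds["DS"].parents:
        scen = parameters.scenario_report(cpds, "DS")
        report["stages"]["scenarios"] = {
            "table": scen.to_dict(orient="records"),
            "contrast_ratio": scen.attrs["contrast_ratio"],
        }
    else:
        report["stages"]["scenarios"] = {"table": [], "contrast_ratio": None}
    if out:
        parameters.save_cpds(cpds, out / "cpds.json")

    # stage 6 — classifiers, evaluation, screening curves per scenario
    y_train = prepped.train.outcome.to_numpy()
    y_test = prepped.test.outcome.to_numpy()
    report["stages"]["models"] = {}
    for name, feats in scenarios.items():
        block: dict = {"features": feats}
        if not feats:
            block["note"] = "empty feature set; scenario skipped"
            report["stages"]["models"][name] = block
            continue
        Xtr = prepped.train_z[feats]
        Xte = prepped.test_z[feats]
        hp, cv_score = classify.hyperparameter_search(
            Xtr, y_train, n_iter=cfg.search_iters, seed=cfg.stage_seed(5), k=cfg.cv_folds
        )
        model, cv = classify.train_model(Xtr, y_train, hp, seed=cfg.stage_seed(6), k=cfg.cv_folds)
        train_eval = classify.evaluate(model, Xtr, y_train)
        test_eval = classify.evaluate(model, Xte, y_test)
        curve = screening.tradeoff_curve(y_test, model.predict_proba(Xte))
        block.update(
            {
                "hyperparams": vars(hp),
                "search_cv_auc": cv_score,
                "threshold": model.threshold,
                "cv_folds": [dataclasses.asdict(f) for f in cv.folds],
                "cv_mean": cv.mean,
                "cv_sd": cv.sd,
                "train": dataclasses.asdict(train_eval),
                "test": dataclasses.asdict(test_eval),
                "curve": curve.table.to_dict(orient="records"),
            }
        )
        if out:
            model.to_json(out / f"model_{name}.json")
            curve.table.to_csv(out / f"curve_{name}.csv", index=False)
        report["stages"]["models"][name] = block

    if out:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=_jsonable))
        (out / "report.md").write_text(_markdown_report(report))
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    return str(o)


def _markdown_report(report: dict) -> str:
    lines = ["# Prescreening pipeline report", ""]
    if report["deviations"]:
        lines += ["**Deviations from defaults:** " + "; ".join(report["deviations"]), ""]
    st = report["stages"]
    lines += [f"- respondents sampled: {st['synthesize']['n']}"]
    lines += [f"- planted Markov blanket: {', '.join(st['synthesize']['planted_mb'])}"]
    lines += [f"- train/test after preparation: {st['prepare']['n_train']} / {st['prepare']['n_test']}"]
    lines += [f"- learned edges: {st['structure']['edges']}", ""]
    for name, block in st.get("models", {}).items():
        lines += [f"## {name}", f"features: {', '.join(block['features']) or '(none)'}"]
        if "test" in block:
            t = block["test"]
            lines += [
                f"threshold {block['threshold']:.3f}; test sensitivity {t['sensitivity']:.3f}, "
                f"specificity {t['specificity']:.3f}, AUC {t['auc_roc']:.3f}",
                "",
            ]
    return "\n".join(lines) + "\n"
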