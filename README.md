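# bnscreen

Bayesian-network prescreening for depressive symptomatology from general
health and sociodemographic survey data.

## The problem

Depression screening instruments such as the PHQ-9 (nine items scored 0–3;
a sum ≥ 10 is the usual cut-off for depressive symptomatology, DS) are not
always available, while routine health-platform data — mobility problems,
sleep medication, chest pain, self-perceived age — are abundant. `bnscreen`
implements a prescreening methodology for that setting: learn which survey
features carry information about DS, quantify the risk probabilistically,
train a calibrated linear classifier, and rank a cohort so that screening
interviews go to the people most likely to need them.

The pipeline:

1. **Preparation** — 70/30 train/test split; outcome = 1(PHQ-9 sum ≥ 10)
   for adults who answered all nine items; drop depression-related columns,
   columns/respondents with > 20 % missing values, and single-level
   columns; quartile-bin numerics with > 30 levels; ordinal-encode with a
   missing class at code 0; z-standardize (training statistics only).
2. **Feature selection** — IAMB Markov-blanket discovery with the
   conditional mutual-information G-test, G = 2·N·MI(X;Y|Z), edge
   confidence from a 1000-replicate bootstrap (keep strength ≥ 50 %, orient
   with the majority), and a final marginal-independence prune at P ≥ .05.
   Two candidate feature sets are read off the graph: the outcome's Markov
   blanket (parents, children, spouses) and every feature connected to the
   outcome by an undirected path ("all-path features").
3. **Probabilistic insight** — Bayesian CPD estimation (Dirichlet prior,
   P(DS | parents) = (n + ess/K)/(N + ess)) and ranked scenario tables:
   how much more likely is DS under the all-risk-factor configuration than
   the all-protective one.
4. **Prediction** — linear SGD classifier (hinge / log / modified Huber ×
   L1 / L2 / elastic net, α ∈ [10⁻⁶, 10⁶]) tuned by 5-fold
   cross-validated AUC with minority oversampling inside training folds,
   Platt-calibrated on out-of-fold scores, thresholded at the across-fold
   mean of the per-fold Youden maximizers J = sensitivity + specificity − 1.
5. **Screening application** — rank the cohort by predicted probability.
   With prevalence DSi, finding TP cases costs TP + FP interviews instead
   of the TP/DSi a random approach needs in expectation, a reduction of

   R = 1 − DSi·(TP + FP)/TP.

   Reference example: 4 cases found in 5 ranked interviews at 10 %
   prevalence versus 40 random interviews → R = 87.5 %.

Because real survey microdata cannot ship with the package, a synthetic
generator (`bnscreen.synthetic`) draws survey-like cohorts from a known
discrete network — a latent DS state with a planted Markov blanket,
observed only through nine PHQ-9-style items — so every stage can be tested
against exact ground truth (planted blanket, exact CPDs, closed-form Bayes
AUC).

## Worked example

```python
import bnscreen as bn

spec = bn.example_spec(seed=1)                    # 10-node planted network
network = bn.make_ground_truth_network(spec)
data = bn.sample_survey(network, 20000, seed=100)
prepped = bn.prepare(data, bn.PrepConfig(seed=3))

disc = prepped.discrete_train("DS")
conf = bn.bootstrap_confidence(disc, B=50, seed=7)
graph, _ = bn.average_network(conf)
graph = bn.prune_by_independence(graph, disc)
print(sorted(bn.markov_blanket_of(graph, "DS").all()))

cpds = bn.fit_cpd_bayes(graph, disc, ess=1.0)
print(bn.scenario_report(cpds, "DS").head(2).to_string(index=False))

y = prepped.train.outcome.to_numpy()
hp, _ = bn.hyperparameter_search(prepped.train_z, y, n_iter=8, seed=19)
model, cv = bn.train_model(prepped.train_z, y, hp, seed=20)
ev = bn.evaluate(model, prepped.test_z, prepped.test.outcome.to_numpy())
print(f"threshold {model.threshold:.3f}: test sensitivity {ev.sensitivity:.3f}, "
      f"specificity {ev.specificity:.3f}, AUC {ev.auc_roc:.3f}")

curve = bn.tradeoff_curve(prepped.test.outcome.to_numpy(),
                          model.predict_proba(prepped.test_z))
point = bn.target_sensitivity_report(curve, 0.80)
print(f"at sensitivity {point['sensitivity']:.2f}: "
      f"{point['R_percent']:.1f}% fewer screening interviews")
```

Output:

```
['age_felt', 'back_pain', 'balance_problem', 'chest_pain', 'sleep_meds', 'usual_activities']
 age_felt  balance_problem  p_positive
        3                2    0.578118
        2                2    0.071136
threshold 0.199: test sensitivity 0.957, specificity 0.953, AUC 0.989
at sensitivity 0.81: 88.4% fewer screening interviews
```

The bootstrap-averaged network recovers the planted six-feature Markov
blanket exactly. The scenario table conditions on the outcome's learned
parents (ordinal codes; higher = more severe): respondents who feel old
and report balance problems carry a 58 % DS probability against 7 % one
level down. The classifier operates at the averaged Youden threshold
0.199, and ranked screening at 81 % sensitivity needs 88 % fewer
interviews than random screening of this 10 %-prevalence cohort.

The same run is available from the shell:

```bash
prescreen run --seed 5 --n 20000 --b 50 --out runs/demo
```

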