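# Methods

This note documents the models and procedures implemented in `bnscreen`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Outcome definition and preparation

The binary target is depressive symptomatology (DS): the sum of nine
PHQ-9-style items (each 0–3) at the conventional cut-off of ≥ 10.
Respondents qualify only if all nine items are answered and age ≥ 18
(`min_age`, applied when an age column is present). The split is 70/30,
drawn uniformly with the training size floored.

Filters run in a fixed order — depression-related columns (by declared
role), columns with missing fraction **strictly** above 20 %, respondents
strictly above 20 % missing over the remaining columns, then single-level
columns — because the outcome of the row filter depends on which columns
survive. Numeric columns with more than 30 distinct observed values are
cut at the training data's 25/50/75th percentiles into four right-closed
bins. All features are then mapped to consecutive integer codes starting
at 1 in declared (else sorted observed) level order; missing entries get
the dedicated code 0, so a raw value of 0 is shifted up rather than
colliding with the missing class. Structure learning consumes these
discrete codes; the classifier consumes their z-scores under training
means and standard deviations. Every fitted artifact (quartile edges,
encoding maps, moments) derives from the training partition alone.

## Structure learning

Conditional independence is tested with the mutual-information G-test:
G = 2·N·MI(X;Y|Z) in nats from empirical frequencies (zero cells
contribute nothing), referred to a chi-square with
(r_x−1)(r_y−1)·∏r_z degrees of freedom over observed level counts. All
tests share α = 0.05, matching the edge-pruning level, since no separate
level is specified anywhere for discovery.

IAMB discovers each node's Markov blanket by greedy growth (admit the
candidate with the largest significant conditional G given the current
blanket) followed by shrinkage (remove members whose test given the rest
is non-significant), iterated to a fixpoint. The skeleton uses the
conservative AND symmetry rule (X–Y only if each is in the other's
blanket); candidate neighbours are confirmed by searching for a
separating subset inside the smaller blanket. V-structures X→Y←Z are
oriented when Y is absent from the separating set of non-adjacent X, Z,
and orientations propagate by the standard rules (no new v-structures, no
cycles); without background knowledge the first three rules are
sufficient, so only they are implemented. Orientations that would create
a directed cycle are skipped.

Edge confidence comes from a nonparametric bootstrap: B full-size
resamples (default 1000), one learned graph each. *Strength* of a pair is
the fraction of replicates containing the edge in either direction;
*direction* is the fraction of a given orientation among those, with
undirected leftovers counting ½ to each side. The averaged network keeps
pairs with strength ≥ 0.5, oriented with the majority; exact 50/50 ties
go to the lexicographically smaller source and are logged, and any cycle
among majority orientations is broken at its weakest-strength edge
(logged). A final sweep removes edges whose **marginal** pairwise G-test
has P ≥ .05 — the literal "between every pair of nodes" reading; a
conditional variant (conditioning on the child's other parents) is
available behind a flag.

Two feature sets are read off the final graph: the outcome's Markov
blanket (parents, children, spouses — co-parents of children not linked
to the outcome), and the all-path features (the outcome's connected
component in the undirected skeleton).

## Parameter learning and scenarios

CPDs are posterior means under a uniform Dirichlet prior with equivalent
sample size `ess` (default 1 — minimal smoothing, since no prior strength
is specified anywhere): P(child=k | config) = (n_k + ess/K)/(n + ess).
Unobserved parent configurations fall back to the uniform prior row;
ess → 0 recovers maximum likelihood. Scenario queries condition on the
outcome's *parents* in the learned graph (the CPD's natural
conditioning set); the scenario report ranks every parent configuration
by P(DS = 1) and reports the max/min contrast ratio.

## Classifier

A linear model is fitted by stochastic gradient descent over three losses
(hinge; log; modified Huber) and three penalties (L1; L2; elastic net)
with α searched log-uniformly over [10⁻⁶, 10⁶]. Search candidates are
scored by mean stratified 5-fold cross-validated AUC, with the minority
class oversampled (duplication with replacement to parity) strictly
inside each training fold. The search strategy is pluggable behind a
fixed scoring contract; the shipped strategy is log-uniform random
search.

Optimization uses a stall-adaptive constant step (eta0 = 0.05, capped at
1/α for stability of the penalty update) with Polyak–Ruppert averaging.
The conventional 1/(α·t) decay was evaluated first and rejected: its step
size scales like 1/α, which made fits at the small-α end of the searched
range seed-dependent (train AUC varying by ~0.015 across restarts);
under the adaptive-averaged scheme every loss converges to the same
optimum to four decimals.

Probabilities come from a Platt sigmoid p = 1/(1+exp(A·f+B)) fitted by
maximum likelihood on **out-of-fold** decision values, so the calibration
map is never optimistically steep; for the log loss the native sigmoid
would be available, but the calibrated map is used uniformly. The
operating threshold is chosen per validation fold by maximizing the
Youden index J = sensitivity + specificity − 1 over midpoints of
consecutive distinct probabilities (plus the endpoints; ties to the
smallest candidate), and the across-fold mean threshold is the single
operating point at which all fold metrics, the whole-training-data
metrics, and the held-out test metrics are reported. Reporting fold
metrics at the averaged (deployed) threshold rather than at each fold's
own is what makes the three blocks comparable.

## Screening application

Ranked screening orders the cohort by predicted probability (stable
ties). With prevalence DSi, identifying TP cases randomly costs TP/DSi
interviews in expectation, against TP + FP down the ranked list, giving
the reduction R = 1 − DSi·(TP+FP)/TP, reported in percent. R is undefined
at TP = 0 (the matched random baseline degenerates) and such thresholds
are flagged rather than forced to a number. The trade-off curve evaluates
sensitivity, specificity and R at every candidate threshold and marks
where the model beats random screening (R > 1 − sensitivity). The
target-sensitivity report returns the threshold attaining a requested
sensitivity with maximal reduction — the boundary threshold before
sensitivity drops below the target. Prevalence defaults to the cohort's
empirical rate; a population value can be supplied for deployment.

## Synthetic ground truth

The generator draws survey-like cohorts from a known discrete DAG. A
binary latent DS state has declared parents, children and spouses:
parents and spouses are categorical roots with Dirichlet(5)-drawn
marginals; the outcome is logit-additive in rescaled parent levels with
slope `effect_size` (default 2; the recovery experiments use 3, the
"high" end) and an intercept solved exactly so the marginal prevalence
hits `prevalence` (default 0.10, matching the reference screening
cohort); children are softmax-monotone in the DS state and their
co-parent spouses. DS is never observed directly: nine PHQ-9-style items
are emitted i.i.d. given the latent state and the recorded outcome is
their sum at cut-off ≥ 10. The emission treats the instrument as highly
reliable (P(sum ≥ 10 | DS=1) ≈ 0.99996, ≈ 0.00065 under DS=0): with a
noisier emission the recorded outcome no longer d-separates parents from
children and systematic spurious edges appear — a faithfulness failure of
the *proxy*, not of the learner. Nuisance columns exercise the
preparation rules: constants, an integer age column (18–90, > 30 levels),
further high-cardinality numerics, and noisy depression-related proxies
of DS (dropped by role). Missingness is injected completely at random
(per-column rates, plus a respondent mechanism that masks half the cells
of a selected fraction of rows, producing the heavily incomplete
respondents the row filter targets); nothing informative is modelled, as
no missingness mechanism is characterized for the real surveys.

Because the network is known, exact oracles exist: the observed-outcome
CPD (emission-mixed), and the Bayes-optimal AUC by enumeration of the
blanket's joint distribution. The canonical test configuration
(`example_spec`) has 10 nodes: two parents, two children, two spouses,
three independent nuisance features.

What passing these tests shows: the primitives match brute-force oracles;
the learner recovers a *recoverable* structure (strong effects, MCAR
missingness, no latent confounding beyond the emission, independent
nuisance features) at n = 20 000; parameters converge; the classifier
tracks the Bayes optimum when the posterior log-odds are near-additive.
What they do not show: performance under informative missingness,
correlated nuisance features, weak effects, survey weighting, or
distribution shift between training and deployment cohorts — all present
in real survey data.

## Problem sizes and numerics

The recovery experiments use n = 20 000 respondents (50 replicates for
blanket recovery; 20 seeds × 50 bootstrap replicates for skeleton
confidence) and n = 50 000 for parameter recovery — sizes comparable to
the national-survey cohorts the methodology targets and large enough that
Monte-Carlo error is well inside the asserted tolerances. Contingency
tables are accumulated by mixed-radix bincount (O(n) per test); very
large conditioning products are compressed to observed strata, with
degrees of freedom always from the declared level counts. CPD rows are
validated to sum to 1 within 1e-9. Determinism: every stochastic step
takes an explicit seed, and the pipeline derives per-stage seeds from one
global seed via `numpy.random.SeedSequence`.

## Known limitations

- The AND adjacency rule is conservative; sparse true graphs with weak
  edges will lose recall before precision.
- Scenario tables condition on learned parents only; if bootstrap
  averaging orients a true parent edge outward (direction confidence is
  much weaker than presence confidence), that feature leaves the
  conditioning set even though it stays in the blanket.
- The reduction statistic presumes the deployment cohort's prevalence is
  known or well estimated; it is a point summary, not an inferential
  quantity.
- Oversampling by duplication changes the effective sample size seen by
  the SGD objective; no correction is applied, matching the methodology
  being replicated.
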