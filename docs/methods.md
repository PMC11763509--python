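# Methods

## Decision problem

One decision per patient: which of four TKI actions (line × generation
cross) to recommend for an EGFR-mutant advanced-NSCLC patient, judged by
the dichotomized endpoint *progression-free for at least 12 months*. The
package treats this as offline policy learning from a flat retrospective
table; no treatment sequences, toxicity or overall survival are modelled.

## Synthetic cohort generator

Real cohorts of this kind are access-restricted, so the generator is a
first-class module, not a test fixture. It emulates a realistic cohort's
*marginal* structure:

- age ~ N(62.7, 11.4), clipped to [25, 95] years;
- binary marginals: female 0.522, ECOG 2–4 0.167, Exon-19 mutation 0.642,
  current smoker 0.368, ≥4 metastases 0.535, bone/liver metastases 0.569,
  brain metastases 0.371, significant comorbidity 0.102;
- NLR log-normal with median 3.2 and mean 3.9 (mu = ln 3.2,
  sigma = sqrt(2 ln(3.9/3.2)) ≈ 0.63); lymphocyte counts log-normal around
  a median of 1400/µL (sd 0.35 on the log scale) and neutrophils
  back-solved as NLR × lymphocytes, because absolute count distributions
  are rarely published;
- recorded action drawn from (0.635, 0.148, 0.047, 0.170) over codes 0–3;
  later-line patients get line 2–5 with a short tail.

Features are sampled independently given the stratum; **joint clinical
correlations are deliberately not modelled**. Passing tests therefore show
that the pipeline recovers planted structure from marginally realistic
data, not that it would perform identically on correlated real cohorts.

The outcome is planted: an `effect_table` maps each stratum
(mutation × line group) and action to P(progression-free ≥ 12 months). The
defaults give the higher-generation action within each line a 10–25 point
advantage, making action 1 optimal for first-line strata and action 3 for
later-line strata — so the optimal policy is known exactly
(`planted_policy`) and policy recovery is testable. Latent progression
times consistent with the drawn outcome (12 + Exp(8) months if
progression-free, 12·Beta(1.8, 1.2) otherwise) are combined with an
independent Uniform(0.3, 30) censoring time applied to a `censor_prop`
(default 0.15) fraction of patients; censoring is what produces the
excludable short-follow-up rows the inclusion filters must handle.

## Inclusion rules and engineering

Kept rows have complete required fields, follow-up ≥ 1 month, and an
evaluable endpoint (progression/death before 12 months, or follow-up ≥ 12
months). Each excluded row is logged with the first failing rule, and
kept + excluded always partition the input. Both log transforms use the
natural log (the base affects scale only), and the 12-month boundary is
inclusive on the progression-free side: a progression event at exactly 12.0
months counts as a progression-free year. The NLR is assumed already
measured in the pre-treatment window; no date arithmetic is done. The
NLR-by-progression test is the pooled-variance (Student) two-sample t-test
with df = n₀ + n₁ − 2, matching the classical degrees of freedom
bookkeeping; Welch's correction is intentionally not used.

## Balancing and split

SMOTE (k = 5 neighbours by default, the canonical choice) equalizes the
progression classes: synthetics are uniform interpolations between a
minority row and one of its k nearest minority neighbours, with neighbour
search in standardized Euclidean space and interpolation in the original
feature space. Binary indicator columns (and the categorical action code)
are snapped to the nearest observed level after interpolation. Balancing is
applied to the **full** engineered table before the 90/10 stratified split,
mirroring the workflow in which the balanced set is built first and 90% of
it used for modelling; this leaks synthetic neighbours of holdout rows into
training, so a leakage-free `split_first=True` mode (split, then balance
the training part only) is available and recommended for any honest
generalization estimate. The training size is round(0.9·n) with
largest-remainder allocation across strata, so 392 balanced rows yield
exactly 353 training cases.

## Screening

Extremely randomized trees (100 trees, Gini impurity, no bootstrap) with
normalized mean-impurity-decrease importances; evaluation by stratified
10-fold cross-validation (accuracy, AUC, recall, precision, F1, kappa,
MCC). The constant-positive dummy baseline pins the panel's floor: AUC is
exactly 0.5 analytically because all scores are tied, recall 1, kappa and
MCC 0. The wider model-zoo comparison that motivates choosing a tree
ensemble is out of scope; only the ensemble and the dummy floor are
implemented.

## Reward shaping and its central caveat

Defaults: match_good 15, match_bad 10, mismatch 12, generation bonus 1
(actions 1 and 3), optional line-inconsistency penalty 2 in "penalized"
mode. The ordering encodes: observed progression-free years are best,
observed early progression worst among matches, and unobserved
counterfactual actions sit in between; the bonus encodes external evidence
favouring newer-generation agents. The magnitudes put Q-values in the low
teens, which is convenient for reading summaries but carries no meaning —
only the ordering shapes the policy.

**Off-policy gap.** The data contain no counterfactual outcomes. Assigning
a fixed neutral reward to mismatched actions is a modelling choice, and the
learned policy inherits it: for a patient stratum whose recorded care
mostly failed, any alternative action looks better at reward 12 regardless
of whether it would actually work. `RewardConfig.counterfactual` accepts a
(record, action) → reward hook for plugging in an outcome model; nothing in
this package estimates counterfactuals itself.

Line branching is implemented as action masking by recorded line (default),
with the reward-penalty variant kept for experimentation.

## DQN

Two hidden layers of 64 ReLU units and a 4-unit linear output, trained for
50,000 timesteps, replay capacity 10,000, batch 32, target-network sync
every 500 steps, Adam at 1e-3 — standard small-problem DQN settings.
Boltzmann temperature τ defaults to 2.0, which keeps all four actions
visited given reward gaps of order 1–5. The learning rate is annealed
linearly to 2% of its initial value: rewards vary within each
(state, action) cell, so a constant step size leaves Adam oscillating
around the TD fixed point with an error of a few tenths, while annealing
brings the per-cell error of the discrete four-stratum fixture under ~0.2
at 50,000 steps. Because every episode is terminal, the TD target is the
immediate reward and γ (kept at 0.99 for interface completeness) cannot
affect the fixed point. All randomness — initialization, exploration,
patient sampling, replay sampling — flows from a single seeded generator;
training is bit-reproducible for a fixed environment and platform
(cross-platform agreement is only to floating-point tolerance). A
non-finite loss aborts with diagnostics rather than continuing silently.

Problem sizes were chosen to keep each training run light: cohorts of a few
hundred patients and 50,000 one-step episodes train in well under a minute
on one CPU, and the test suite shares its trained models across tests.

## Reporting definitions

- **Q summary**: per-action mean/sd/min/max of Q over a state set.
- **Action frequencies**: greedy masked choices split by recorded line;
  masked actions have structurally zero counts.
- **Partial dependence**: overwrite one feature with each grid value in
  every state (on the standardized scale via the stored scaler) and average
  Q per action.
- **Policy AUC**: each patient scored by Q at their *recorded* action,
  ranked against the progression-free-year outcome. There is no canonical
  AUC for an RL policy; this recorded-action-value definition is this
  package's own, chosen because it asks whether the learned values rank
  observed care by its observed success. On training data it is close to 1
  (the network can memorize outcomes through the match rewards); only
  held-out states give a meaningful number.
- **Recommendation**: masked argmax of Q, ties to the lowest action code,
  with the full Q-vector and the masked actions reported for transparency.

## Known limitations

- Synthetic cohorts have independent features given the stratum; real
  predictive structure (e.g. NLR–outcome coupling) is absent unless
  planted, so partial-dependence shapes on synthetic data are not clinical
  findings.
- The mismatch reward makes the policy's preferences for unobserved actions
  an artifact of reward shaping plus generalization, not causal inference.
- SMOTE-before-split reproduces a common published workflow but inflates
  holdout estimates; use `split_first` for any real evaluation.
- The balanced table feeds both the classifier screen and the RL
  environment; synthetic patients carry rounded categorical codes and are
  indistinguishable from real rows downstream by design.
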