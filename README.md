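# tkirec

Offline reinforcement-learning treatment recommendation for EGFR-mutant
advanced non-small cell lung cancer (NSCLC).

Patients whose tumours carry an activating EGFR mutation are treated with
tyrosine kinase inhibitors (TKIs), but two choices remain genuinely open at
the bedside: which TKI **generation** to give (first vs second-or-higher)
and in which **treatment line** (first systemic therapy vs after
chemotherapy). `tkirec` learns a recommendation policy for this decision
from flat retrospective patient tables, and ships a synthetic-cohort
generator so the entire pipeline is testable without access to protected
clinical data. It is aimed at biostatisticians and ML researchers studying
offline RL for clinical decision support, not at clinical use.

## The model

Each patient contributes one decision. The four actions cross line with
generation:

| code | action |
|------|--------|
| 0 | first-line, first-generation TKI |
| 1 | first-line, second- or higher-generation TKI |
| 2 | second- or later-line, first-generation TKI |
| 3 | second- or later-line, second- or higher-generation TKI |

The outcome is the dichotomized progression-free survival (PFS) endpoint
`progression_category` (0 = progression-free ≥ 12 months). States are
standardized clinical features: log-age, log neutrophil-to-lymphocyte ratio
(NLR), treatment line, ECOG status, mutation category, smoking, metastasis
burden and sites, comorbidity.

Because the data record a single decision per patient, the environment is a
one-step episodic contextual bandit: an episode samples a patient uniformly,
the agent picks an action *a*, receives the shaped reward

```
r(s, a) = match_good·[a = a_rec, y = 0] + match_bad·[a = a_rec, y = 1]
        + mismatch·[a ≠ a_rec] + g·[a ∈ {1, 3}]   (− line penalty, optional)
```

(defaults 15 / 10 / 12 / 1), and the episode terminates. A deep Q-network
(two hidden layers of 64 ReLU units, four linear outputs) is trained for
50,000 timesteps with experience replay, a periodically synced target
network and Boltzmann exploration, P(a) ∝ exp(Q_a/τ). For terminal one-step
episodes the TD target reduces to the immediate reward, so Q(s, a) converges
to the expected shaped reward — a property the test suite checks against a
brute-force oracle. Actions whose line half contradicts the patient's
recorded line are masked (first-line patients choose between 0 and 1,
later-line patients between 2 and 3).

Around the RL core the package implements the standard cohort workflow:
inclusion filters (≥ 1 month follow-up; evaluable one-year endpoint), SMOTE
oversampling of the minority progression class, a stratified 90/10
modelling split, and an extremely-randomized-trees screen with
impurity-based feature importances plus a constant dummy baseline.

## Worked example

```
$ tkirec simulate --n 318 --seed 0 --out cohort.csv
$ tkirec engineer --in cohort.csv --out engineered.csv --exclusions excluded.csv
INFO kept 306 of 318 rows (12 excluded)
$ tkirec balance --in engineered.csv --out balanced.csv --seed 0
INFO added 66 synthetic minority rows -> 372 total
$ tkirec train --in balanced.csv --model-out model.json --seed 0
INFO trained 50000 timesteps; final mean reward 13.558
$ tkirec report --model model.json --in balanced.csv --outdir reports
      action_0  action_1  action_2  action_3
mean     11.85     13.67     11.42     13.92
sd        3.51      2.24      2.20      2.34
...
```

The Q-summary rows say that, averaged over this cohort, the two
higher-generation actions (1 and 3) carry the largest expected shaped
rewards — the policy has learned the generation effect planted in the
synthetic cohort. Action frequencies in `reports/action_frequencies.csv`
show the same thing per scenario (first-line: 185 of 312 greedy choices are
action 1; later-line: 40 of 60 are action 3). Note that the policy AUC
printed by `report` is computed on the table you pass in; on the training
table itself it is near 1.0 and optimistic — score a held-out table for an
honest figure (the 90/10 split of this example gives ≈ 0.70).

A single-patient recommendation (the cohort's modal later-line profile):

```
$ tkirec recommend --model model.json --patient patient.json
{
  "action": 3,
  "label": "second- or later-line, second- or higher-generation TKI",
  "q_values": [22.17, 16.26, 12.07, 14.91],
  "scenario": "later-line",
  "masked_actions": [0, 1]
}
```

Actions 0 and 1 are masked because this patient is past first-line therapy;
among the available actions the higher-generation TKI (Q = 14.91 vs 12.07)
is recommended. The unmasked Q-values for actions 0–1 are extrapolations
and are reported only for transparency.

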