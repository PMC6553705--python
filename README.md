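# netwell

Does the *structure* of a person's communication network — how many people
they talk to, how clustered or central they are — carry information about
their physical behavior and wellness, beyond what a wearable already
measures? `netwell` is a pipeline for answering that question on
longitudinal cohort data: weekly communication graphs from call/text logs,
weekly behavioral summaries from minute-level wearable streams, a
cross-correlation framework linking the two, and an ordinal wellness-state
predictor built on a weighted-voting classifier ensemble. A synthetic-cohort
simulator with plantable effect sizes makes every stage testable without
access to sensitive study data.

It is aimed at computational social scientists and digital-phenotyping
researchers working with event logs + wearable exports + survey outcomes.

## The method

**Networks.** Calls and texts pool into one undirected, unweighted graph per
7-day week; pairs with fewer than 3 events over the whole window are dropped
as spurious. Both a *whole* network (external contacts included) and a
*participant* network (enrolled roster only) are built, and five structural
features are computed per person-week: degree, triangles, clustering
coefficient, betweenness and (component-scaled) closeness centrality.

**Behavior.** Device days with under 1140 worn minutes (80% wear) are
discarded; the rest yield 12 weekly features: mean/variance of minute heart
rate, mean/sd of daily steps, and mean/sd of daily minutes in each of four
activity states.

**Coupling (RQ1).** For all 60 (structure, behavior) feature pairs, the
zero-lag normalized cross-correlation

r(x, y) = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²)

of the cohort weekly mean series, with threshold counts at |r| ≥ 0.5 / 0.7,
per-person counts, and median-split Welch t-tests with Benjamini–Hochberg
correction.

**Prediction (RQ2).** Each wellness attribute (stress, happiness, positive
attitude, health; Likert 1–4 or 1–5) is predicted from participant-week
feature vectors under three feature sets (gender+behavior, network-only,
all). Five tuned base classifiers (KNN, CART, SVM, LR, RF) are ranked by
5-fold CV accuracy; the top three vote through

y_vote = argmax_j Σᵢ w_ij p_ij,  Σ w = 1,

with the weights w selected on held-out folds from a step-0.1 simplex grid.
Performance is macro and per-level F1 against a uniform-random baseline
(closed form 2p/(Kp+1) per class).

## Worked example

Simulate a 60-participant, 22-week cohort with strong structure–behavior
coupling and network-dependent labels, then run the whole pipeline:

```python
import json
from pathlib import Path
import pandas as pd
from netwell import GeneratorConfig, RunConfig, run_pipeline

config = RunConfig(
    out_dir=Path("demo_run"),
    seed=4,
    simulate=GeneratorConfig(n_participants=60, n_external=120, n_weeks=22, seed=4),
    grid="none",            # fixed hyper-parameters; "full" enables the grid search
    attributes=("stress",),
)
out = run_pipeline(config)

summary = json.loads((out / "correlation_summary.json").read_text())
print("pair counts:", summary["pair_counts"])
m = pd.read_csv(out / "correlation_matrix.csv")
row = m[(m.structure_feature == "degree_participant")
        & (m.behavior_feature == "steps_mean")].iloc[0]
print(f"degree(participant) vs steps: r={row.r:.2f} p={row.p:.2e}")
print(pd.read_csv(out / "prediction_report_stress.csv", index_col=0).to_string())
```

Output:

```
pair counts: {'0.5': 54, '0.7': 42}
degree(participant) vs steps: r=0.97 p=2.10e-14
                                                   F1  Level1  Level2  Level3  Level4
random generation baseline                       0.21     0.0    0.27    0.32    0.27
gender + health behavior data                    0.27     0.0    0.26    0.42    0.39
social network structure                         0.35     0.0    0.48    0.45    0.46
gender + health behavior data + social network   0.44     0.0    0.62    0.50    0.65
improvement                                     63.00     NaN  138.00   19.00   67.00
```

Reading it: with coupling ρ = 0.9 planted in the simulator, 54 of the 60
structure–behavior pairs reach |r| ≥ 0.5 and the cohort degree–steps series
are almost perfectly correlated (r = 0.97). Because the synthetic labels
depend on sociability as well as fitness, adding the 10 network features
lifts the stress macro-F1 from 0.27 to 0.44 — a 63% relative improvement —
while no Level-1 participant landed in this test split (F1 0, improvement
undefined). With `coupling_rho=0` and `label_beta_network=0` the same
pipeline reports ~1 strong pair and no systematic improvement, which is the
control that the analysis is not manufacturing signal.

The same run is available from the shell:

```bash
netwell run-all --config cfg.yaml     # or: simulate / networks / features /
                                      #     correlate / predict, stage by stage
```

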