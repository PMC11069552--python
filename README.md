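# dacl

**Auto-optimized collaborative learning for tabular clinical risk
classification.**

`dacl` is a seed-reproducible pipeline for binary disease prognosis on
mixed-type health-record tables (numeric, binary and categorical columns
with missing cells), aimed at researchers who want a fully synthetic,
ground-truthed testbed for this class of methods.  It chains five
components:

1. **DAEM imputation** — a deep auto-encoder `b = σ(ωa + β)`,
   `c = 𝒟(b) = ω′b + β′`, trained to minimize the masked reconstruction
   loss (squared error on continuous coordinates, cross-entropy on
   discrete ones) with iterative re-feeding of missing inputs; the trained
   reconstruction fills the missing cells.
2. **Golden flower search (GFS) feature selection** — flower-pollination
   search whose global move is a tangent flight
   `G′ = G + s·S·tan θ·(G − τ*)` with Pareto-distributed step magnitudes
   `S` and whose local move is a golden-section line search (probes at the
   0.618/0.382 points) toward a random conspecific, wrapped over feature
   subsets scored by cross-validated accuracy plus a sparsity reward.
3. **ColBGaN classification** — a conditional GAN whose generator consumes
   an additive embedding `γₜ = σ(γ; w_α) + φ(y; w_β)` of noise and label,
   trained in two adversarial pairings (generator–discriminator and
   generator–classifier, the latter weighted by δ), and used both to
   balance minority classes by synthesis and to predict labels.
4. **Water-drop optimization (WDO) tuning** — intelligent-water-drops
   graph search (soil/velocity dynamics `ℑ(v+1) = ℑ(v) + p/(q + o·ζ²)`,
   erosion `ζ ← (1−g_y)ζ − g_y·Δζ`, best-path reinforcement
   `ζ ← (1+g_m)ζ`) over a layered grid graph, selecting the generator loss
   weight δ.
5. **Evaluation** — TP/TN/FP/FN metric suite (accuracy, precision,
   recall/sensitivity, specificity, F1, NPV, MCC, fall-out, miss rate) and
   trapezoidal ROC AUC.

Because public heart-disease/stroke/diabetes datasets come without ground
truth about what is recoverable, the package ships a synthetic cohort
generator that emulates a stroke-registry schema with a planted sparse
logistic signal, known Bayes accuracy, configurable MCAR missingness and
class imbalance — so every stage can be scored against a known answer.
See `docs/methods.md` for the models and the design choices.

## Worked example

```python
from dacl import default_config, run_pipeline

report = run_pipeline(default_config(global_seed=1, output_dir="out"))
print(report.ground_truth["bayes_accuracy_estimate"])  # 0.9470...
print(report.selected_features)
print(report.tuned_delta)
print({k: round(v, 3) for k, v in report.metrics.items() if isinstance(v, float)})
```

prints (seed 1):

```
0.947029299926241
['age', 'hypertension', 'heart_disease', 'avg_glucose', 'bmi']
0.1
{'accuracy': 0.916, 'precision': 0.923, 'recall_sensitivity': 0.908,
 'specificity': 0.924, 'f1': 0.915, 'npv': 0.909, 'mcc': 0.832,
 'fall_out': 0.076, 'miss_rate': 0.092, 'auc': 0.966}
```

Reading: the generated 2,000-patient cohort carries a planted logistic
signal on five risk factors (age, hypertension, heart disease, glucose,
BMI) whose Bayes-optimal accuracy is 94.7%; after imputing the 10% of
cells masked at random, the wrapper selected exactly the five planted
factors and none of the uninformative columns, the water-drop tuner picked
δ = 0.1, and the GAN classifier reached 91.6% test accuracy (AUC 0.966) —
within 3.1 points of the Bayes ceiling.

The same run from the shell:

```bash
dacl run --config configs/default.yaml --seed 1 --out-dir out
```

Individual stages are exposed as `dacl generate | impute | select | tune |
train | evaluate`, exchanging plain CSV/JSON artifacts.

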