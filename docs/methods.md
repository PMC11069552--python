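# Methods

`dacl` implements a five-stage pipeline for binary disease classification on
mixed-type clinical tables: auto-encoder imputation, metaheuristic wrapper
feature selection, conditional-GAN classification with minority
augmentation, graph-search hyperparameter tuning, and a confusion-matrix
metric suite.  This note records the models, the parameter choices that
matter, and the places where the design was genuinely open.

## Tabular encoding

All models operate on an encoded matrix in `[0, 1]^d`: numeric columns are
min-max scaled over *observed* cells (a zero-range column maps to the
constant 0.5 with a warning), binary columns map their declared level order
to 0/1, and categorical columns expand one-hot ("one input per category",
so the problem dimension is fixed by the schema).  Missing source cells
carry a placeholder 0 in every derived column plus a mask bit; the mask,
not the placeholder, carries the information.  Decoding inverts the map:
inverse min-max for numerics, a 0.5 threshold for binaries, arg-max for
one-hot groups.  Missing markers in CSV are exactly `""` and `"NA"`
(case-insensitive); anything else is a value.

## Synthetic cohorts

The generator emulates a stroke-registry schema (id, gender, age,
hypertension, heart disease, marital status, work type, residence, average
glucose, BMI, smoking status, binary stroke label).  Covariates follow a
one-factor Gaussian copula: a latent "age/frailty" factor with loadings
age 0.85, glucose 0.70, BMI 0.70, ever-married 0.55, work type 0.45,
smoking 0.35, hypertension 0.30, heart disease 0.25; gender and residence
load 0 and are therefore exactly independent of the label.  Marginals are
truncated Gaussians for numerics (age ~ N(50, 15²) on [18, 95], glucose ~
N(105, 35²), BMI ~ N(28, 6²)) and fixed multinomials for categories
(hypertension 25%, heart disease 12%, frequencies otherwise matching public
stroke registries).

The label is Bernoulli(logistic(c + Σ βⱼ·xⱼ)) on the encoded scale with a
sparse planted signal: β = (16, 12, 12, 16, 8) on age, hypertension, heart
disease, glucose, BMI.  The scale was chosen once so that (a) the
Bayes-optimal accuracy sits in the low 0.9s at balanced prevalence — sharp
enough that a classifier's gap to the ceiling is measurable — and (b) every
planted feature carries *unique* signal exceeding the feature-selection
sparsity price (verified by drop-one analysis before freezing).  The
intercept is bisected against the fixed uniform draws so the empirical
prevalence matches the requested minority fraction within ±0.02; the Bayes
accuracy estimate is the Monte-Carlo mean of max(p, 1−p) over the cohort.

Missingness is MCAR only: each non-label, non-id cell is masked
independently; pre-masking values stay in the table as hidden truth so
imputation error can be scored.  What the generator does *not* emulate:
real registries' MAR/MNAR missingness, measurement error, longitudinal
structure, and multi-factor covariance.  Passing tests therefore show the
pipeline recovers a known sparse logistic signal under MCAR gaps — not that
it matches any particular public dataset's numbers.

The frailty correlations mean the zero-coefficient columns ever-married,
work type and smoking *do* associate marginally with the label (realistic
confounding); only gender and residence are clean null columns, and the
association property test checks those.

## Auto-encoder imputation

A single sigmoid encoder layer b = σ(Wa + β) and an affine decoder whose
output is linear on continuous coordinates (squared-error loss, no
squashing) and sigmoid on discrete coordinates (cross-entropy loss).  The
loss is restricted to observed cells.  Missing inputs start at observed
column means and are overwritten by the current reconstruction at the end
of each of 3 re-feeding rounds; imputation at inference applies the same
fixed-point refinement (3 rounds) before decoding.

Defaults: bottleneck ⌈d/4⌉, 300 epochs, Adam at 1e-3, batch 64, L2 weight
decay 3e-3.  Two of these deserve explanation.  A *narrow* bottleneck is
essential: with a wide code the network reconstructs each observed cell
from itself, which is loss-optimal but tells missing cells nothing.  The
weight decay damps the same identity shortcut's residual noise, which
otherwise flips near-0.5 sigmoid outputs across the decision threshold and
poisons one-hot decoding.  With both, the network learns the cohort's
shared factor and beats column-mean/mode imputation on hidden truth;
without cross-column correlation no non-denoising auto-encoder can beat
the mean baseline, which is why the generator plants realistic
correlations.  Denoising corruption, stacked layers and variational
variants are deliberately out of scope.

Imputation error is scored as RMSE over masked cells on the encoded scale:
numeric errors divided by the observed column range, category errors as
0/1 mismatch — making mixed-type errors commensurate.

## Golden flower search

Population search over a box, minimizing.  Each pollen takes, with
probability p = 0.8, a **global tangent flight**
G′ = G + s·S·tan(θ)·(G − τ*) with θ ~ U(0, π) per component (tan clipped at
1e3) and S a Pareto(shape 1.5, scale 1) draw — the heavy-tailed step law
and the tangent flight composed into one move; otherwise a **local
golden-section line search** along the segment to a uniformly chosen other
pollen (8 evaluations, classical probe-reuse scheme, probes at the
0.618/0.382 points).  Acceptance is greedy per pollen, so the best-so-far
trace is non-increasing by construction.

θ must span the full (0, π): positive-only tan makes every global step
point *away* from the incumbent best and the search stalls; signed steps
let pollens contract past or toward the best, and the sphere benchmark
then converges to ~1e-16.  The Pareto shape 1.5 keeps a heavy tail with
finite mean.  A `golden_coefficient` override (e.g. 0.0618) exists for
fidelity experiments; coefficients below 0.5 probe the mirrored point
pair.

Feature selection wraps this in [0, 1]^d with threshold-0.5 binarization
(arg-max rescue for the empty mask).  Fitness is
w·(3-fold stratified CV accuracy of a ridge classifier on the subset)
+ (1−w)·(1 − |S|/d), with w = 0.9: at d ≈ 20 the per-feature sparsity
price is 0.005, below what a genuinely informative clinical feature
contributes but enough to prune noise columns.  All-constant subsets fall
back to majority-class accuracy.  Subset scores are cached by mask.

## Conditional GAN classifier

Three dense networks (two hidden layers of 64 leaky-rectified units each).
The generator consumes γₜ = embed(noise) + embed(label) — a learned
per-class vector added to a dense embedding of 16-dim Gaussian noise — and
emits a row through sigmoids, so samples live in the encoded hypercube.
Per batch: (i) the discriminator ascends the real/fake log-loss, and the
empirical minimax value E[D(real)] + E[1 − D(fake)] is logged; (ii) the
classifier descends cross-entropy on real labeled rows; (iii) the
generator descends the non-saturating adversarial loss plus
δ·CE(classifier(fake), intended labels) — the collaboration term — plus a
class-conditional feature-matching penalty (weight 5) that pulls the
generator's per-class output means toward the real per-class means.
Feature matching is what pins the conditional marginals: the adversarial
signal alone left them underdetermined and the generator drifted into
saturated caricatures of the minority class.  δ is additive in the loss
gradient through the classifier only; with δ = 0 and the classifier
update disabled the loop is exactly a plain conditional GAN (regression
test asserts identical loss traces).

Augmentation generates minority-labeled rows until class counts are equal
(real rows untouched, synthetic rows flagged), then the classifier head
alone is refit on the balanced matrix.  Learning rates: 2e-4 for the
adversarial pair, 1e-3 for the classifier; 300 epochs by default, reduced
to ~100–120 in pipeline runs, which the benchmarks show is past the
accuracy plateau on cohorts of this size.

## Water-drop graph search and δ tuning

Drops traverse a directed graph from source to sink.  Edge choice is
multinomial with fitness 1/(ε + shifted soil), the shift anchoring the
candidate minimum at zero once soils go negative; traversal updates
velocity by p/(q + o·soil²), erodes the edge by
soil ← (1−g_y)·soil − g_y·Δsoil with Δsoil = p/(q + o·time²) and
time = cost/velocity; each iteration's best path (quality 1/cost, ties to
the lexicographically smaller node sequence) is reinforced by
soil ← (1+g_m)·soil.  The multiplicative reinforcement is kept in that
literal form: erosion drives good-path soils negative, and amplifying a
negative soil raises its fitness.  That coupling dictates two defaults
that differ from the classical-literature values (which presuppose a
subtractive reinforcement, available behind `classic_global_update`):
initial soil 1.0 — a large positive start makes reinforcement *repulsive*
for many iterations — and ε = 0.5, without which the first edge to go
negative absorbs essentially all probability mass and exploration dies.
With the remaining defaults p=1, q=0.01, o=1, g_y=g_m=0.9 and 20 drops ×
50 iterations, the search matches exhaustive enumeration on ≤8-node
layered graphs.

Hyperparameter tuning builds a layered graph (one layer per grid, one node
per candidate, full bipartite links), so each source–sink path is a
configuration; path quality is the cached validation log-likelihood of a
short (25-epoch) GAN training run, and the best path yields δ*.  The grid
default is {0, 0.01, 0.1, 0.5, 1, 2}.  Tuning runs before final training;
a per-epoch schedule was considered and rejected as underdetermined.

## Pipeline and reproducibility

Stage order: generate → impute → select → tune → train → evaluate.  Every
stage derives its seed as CRC32(global_seed ":" stage_name) mod 2³¹, so
toggling one stage never shifts another's randomness.  Stages exchange
serialized artifacts (CSV/JSON); a failure marks the stage and skips
downstream work.  Two runs with the same config and seed produce identical
reports up to wall-clock timings.  Imputation is fit on the full table
(the stage is unsupervised and precedes the split); scaling min/max are
frozen per encoding, and test rows are clipped to [0, 1].

Benchmark problem sizes (n=500 imputation cohorts, n=1000 selection
cohorts with three appended noise "lab marker" columns for a 20-column
encoded space, n=2000 pipeline and augmentation cohorts, ≤8-node tuning
graphs) were chosen as the smallest scales at which the measured effects
are stable across seed batches.

## Known limitations

- Binary labels only; multi-disease settings are separate binary tasks.
- MCAR missingness only; MAR/MNAR left as an enum extension.
- The GAN matches first conditional moments by construction; higher-order
  structure of generated rows is only as good as the adversarial signal.
- The wrapper objective uses a linear CV classifier; feature sets whose
  value is purely interactive would be under-selected.
- Confidence intervals and calibration curves are not produced.
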