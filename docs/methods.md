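# Methods

## The task and the statistic

The Demonstrative Choice Task (DCT) presents one noun per trial with no
surrounding context and asks the participant to pair it with a demonstrative
form — *this*-like (proximal) or *that*-like (distal), plus a medial form in
3-term languages such as Spanish and Filipino. With no physical referent,
the choice is hypothesized to express *psychological proximity*: how close
the concept sits to the speaker's current mental state.

Each of the 290 task items carries a score on the 65 Binder semantic
dimensions (experience-based features such as *Sad*, *Fearful*, *Happy*,
*Social*, rated roughly 0–6). Choices are coded r ∈ {+1, 0, −1}
(proximal / medial / distal) and aggregated into a per-subject **semantic
profile**:

    P[s, f] = (1 / n_items) * Σ_items r[s, i] * B[i, f]

one value per Binder feature, positive when the subject leans proximal on
items scoring high on that feature. The denominator is always the full item
count, so under the default `drop_medial` coding a medial response
contributes zero to the numerator without renormalizing the scale — medial
responses are ignored, not redistributed. Two alternative codings
(`medial_as_distal`, `medial_as_proximal`) fold the medial form into either
pole; with no medial responses all three coincide exactly, which is tested.

Subjects are labeled by the PHQ-9: nine symptom items scored 0–3, summed;
a sum ≥ 10 defines the depression group (coded 1), below it control
(coded 0).

## Quality control

Three low-effort rules plus a completeness rule, applied with strict
comparisons:

| rule | metric | threshold |
|---|---|---|
| fast responding | fraction of non-check trials with RT < 300 ms | excluded if > 0.10 |
| stereotyped responding | response entropy over chosen forms | excluded if < 0.80 |
| inattention | failed attention checks (of 15) | excluded if > 3 |
| missing data | incomplete demographics/PHQ-9/trials | excluded |

Entropy is Shannon entropy (base 2) of the subject's form distribution
divided by log2(K), K the number of forms in their system, so one 0.80
threshold applies to 2- and 3-term languages alike. Whether the original
threshold was on raw bits or normalized entropy for 3-term systems is not
decidable from the protocol's wording; normalization is this package's
convention and makes the 2-term case (max 1 bit) unchanged. Entropy is
computed over *forms*, not physical buttons, because button labels were
randomized per trial. Attention-check trials are excluded from the RT and
entropy metrics: they have a correct answer and would bias both.

## Synthetic cohorts

The generator (`dctsem.synthetic`) emulates the study conditions so every
stage can be tested against known truth:

* **Languages** — seven samples with realistic cohort sizes by default
  (English 1654 … Filipino 199, total 3881); `scaled_to(n)` preserves the
  proportions at smaller totals. Spanish and Filipino use 3-term systems.
* **Binder matrix** — 290 items × 65 features on [0, 6]. Emotion features
  share a latent per-item valence (loadings ±1.2, residual SD 0.8), giving
  within-block correlations ≈ 0.6–0.7 — the multicollinearity the
  classifiers must tolerate. Other features are independent noise (SD 1.4)
  around the scale midpoint.
* **PHQ-9** — a latent severity s ~ N(0,1) per subject; each item is the
  count of fixed cutpoints (0.5, 1.5, 2.5) below s plus item noise plus an
  offset. The offset is solved deterministically (Gauss–Hermite quadrature
  + convolution + bisection) so expected prevalence of sum ≥ 10 equals the
  target, 0.34 by default. Realized prevalence is binomially noisy around
  it.
* **Choices** — for 2-term subjects, P(proximal | item) =
  logistic(0.2 + α_s + β_group · z(binder_row)) with subject intercepts
  α_s ~ N(0, 0.2); 3-term subjects use proportional odds on the same linear
  predictor with cutpoints (−1.2, 0.55), giving roughly the observed
  45/37/18 proximal/medial/distal split. The default planted truth weights
  +0.4 on *Sad, Fearful, Unpleasant, Pain, Disgusted, Harm* and −0.4 on
  *Happy, Pleasant, Benefit, Drive* for the depression group and 0 for
  controls — the direction signature that recovery tests check. The base
  intercept and intercept SD were chosen so the marginal proximal rate sits
  near the observed ~52% share and so a clean subject crosses the 0.80
  entropy threshold only on a > 4.6 SD intercept draw (~2·10⁻⁶): natural
  low-effort behavior appears in the generator only through explicit
  injection, which keeps the injected ids an exact ground truth for QC.
  For the same reason, attentive subjects' natural check failures are
  capped at 3 (pass probability 0.98 per check otherwise).
* **RTs** — log-normal with meanlog log(600 ms) and sdlog 0.3 (placeholder
  calibration; the protocol fixes no empirical RT distribution). Under these
  values a clean subject's fast-RT fraction exceeding 10% is a ≫ 5σ event.
* **Low-effort injection** — fast responders get 15% of RTs at 100–280 ms;
  constant responders answer one fixed form on 97% of trials; inattentive
  subjects pass checks with probability 0.3 (forced ≥ 4 failures).

What the generator does **not** emulate: lexical content of items,
language-specific semantic norms, RT–semantics coupling, the long positive
profile tails seen in some real samples, culturally varying prevalence, or
natural low-effort behavior. Passing tests therefore demonstrate that the
pipeline recovers planted structure and is correctly null-calibrated — not
that real data contain such structure. The planted effects are also
deliberately stronger than real-data effect sizes (where test F1s sit
near 0.6), because recovery tests need an unambiguous truth.

## Classification

Stratified 70/30 train/test split on (group × language); 20% of the
training set is a validation set for hyperparameter tuning. The training
partition is downsampled to equal class counts (majority sampled without
replacement, minority untouched), anchoring chance accuracy at 0.5 on any
balanced view; the test set is left intact and metrics are reported both
raw and on a seeded class-balanced test view. Where downsampling was
applied in the original pipeline (before or after splitting) is not stated;
train-partition-only is the default here and a `pre_split` switch exists in
the study configuration. Profiles are z-scored with statistics fit on the
balanced training rows only; an audit asserts no test id ever enters
fitting.

Candidates: L2-penalized logistic regression ("ridge"; a thresholded ridge
regression on 0/1 labels is available as a variant), k-nearest neighbors
(tuned on neighbor count, leaf size, weighting), an xgboost tree ensemble
(tuned on n_estimators, learning rate, max depth, and both L1/L2
regularization strengths), and 2-layer (128, 64) and 3-layer (128, 64, 32)
relu networks with sigmoid output (sklearn MLPs; tuned on batch size and
epoch count). Tuning maximizes validation F1 (ROC-AUC by option); ties
resolve to the earliest grid entry; the chosen configuration is refit on
the full balanced training set. The label-shuffled baseline permutes
training labels only and reruns the identical pipeline.

## Interpretation

Feature attributions are exact TreeSHAP values computed natively by
xgboost (`pred_contribs`); per sample they sum to the model's log-odds
margin (asserted at 1e-6 relative to margin magnitude — the values are
float32). Because positive attributions on one class mirror negative ones
on the other, the plain sample mean of SHAP values is ~0 for any
discriminative feature; the headline per-feature summary is therefore the
mean SHAP among test samples *above the feature's median* — positive means
high scores on the feature push predictions toward depression. Mean |SHAP|
is emitted for magnitude ranking, and summaries are over test samples only.

Robustness: each bootstrap run redraws the stratified split (re-splitting,
not case resampling, so each run sees a fresh training and test sample), rebalances, retrains the tuned configuration, and records
metrics and effects; failed runs are recorded, never dropped. Effect tables
are compared across scopes with Spearman rank correlation (Kendall by
flag) and mapped with agglomerative clustering (average linkage, Euclidean
distance) for heatmap ordering.

A known limitation, visible in the recovery tests: with strongly correlated
planted features, greedy trees concentrate attributions on a few block
representatives; a weaker planted feature outside the dominant block (e.g.
*Drive* in the default template) can receive attributions of zero with an
uninformative sign even when its effect is real. Bootstrap averaging
spreads selection within a correlated block but does not resurrect features
the trees never use.

## Replication arm

The word-level analysis reduces the subjects × items response matrix with
centered PCA (components retained to 90% cumulative variance by default;
the count is configurable) and fits four logistic
variants: `mDCT` (component scores), `mDCT+GenderAge` (plus z-scored age
and one-hot gender, largest category as reference), `mGenderAge`, and
`mRandomBaseline` (shuffled training labels). Accuracy — the replication
arm's headline metric — is bootstrapped over re-drawn splits with balanced
training and balanced test views; means, SDs and percentile 95% CIs are
reported. Component-space coefficients are back-projected through the
loadings to word space (exactly reproducing the linear predictor), ranking
the words most predictive of each group. No logistic regularization beyond
sklearn's default L2 (C = 1) is applied.

## Embedding → Binder extrapolation

Items without human Binder ratings get predicted scores from word
embeddings: six candidate regressors (linear, ridge, kNN, boosted-tree
multi-output, and 2- and 3-layer networks, the 3-layer network being the
conventional winner for this task; families and hyperparameters are
configurable) are trained on rated words with all task items excluded,
scored by mean R² across the 65 dimensions on a seeded 80/20 held-out
split, and the best is refit and used for prediction. An
audit asserts the training word list is disjoint from the excluded items.
Tests run on a synthetic fixture (Gaussian embeddings with a planted
linear norm map); real embedding files are an optional input, never
required.

## Numerical and reproducibility choices

One global seed; every stochastic operation derives a child seed from it
via `SeedSequence` over (seed, stage-name, index), so stages are
independent and bit-reproducible; all derived seeds are < 2³¹. xgboost runs
single-threaded with `tree_method="hist"` for determinism. Constant
features z-score to zeros rather than erroring. Degenerate evaluation
subsets (a language absent from a test set, a class empty) are flagged
absent, never fabricated. Repeated answers to one item fail loudly rather
than being averaged.

Problem sizes used by the test-suite and the acceptance script — cohorts
of 300–1500 subjects and 50–100 bootstrap runs instead of the study-scale
3881 subjects and 1000 runs — are the package's desk-scale defaults; the
statistics checked (chance anchoring, null calibration, sign recovery) are
size-stable at these n.
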