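# Methods

This note documents the models and procedures implemented in `mrdflow`:
the synthetic cytometry generator, the event classifier and its training
rule, the hybrid case-level decision logic, and the validation statistics.
It also records the numerical choices and the design decisions that were
genuinely open, and states what the synthetic experiments do and do not
demonstrate.

## 1. The generative model (`mrdflow.simulate`)

### Intensity model

Each of the 14 cell classes has a per-channel template: the log10
intensity of channel *c* for an event of class *k* is drawn
N(μ_kc, σ_kc), exponentiated, and clipped to the 18-bit instrument range
[0, 262143]. Locations follow the conventional staining vocabulary
(negative ≈ 10^1.2, dim ≈ 10^2.3, positive ≈ 10^3.2, bright ≈ 10^3.9);
spreads are 0.18 log10 for fluorescence (≈ 50% CV) and ~0.10–0.12 for
scatter. Surface light-chain structure is a mixture: the CLL clone is
dim-kappa restricted (kappa dim-positive, lambda negative); polytypic B
cells draw kappa- or lambda-positive modes 60:40, a near-physiologic
ratio.

The CLL template is the canonical phenotype: CD5+ CD19+ CD20-dim CD22-dim
CD43+ CD200-bright, dim light-chain restriction. The **atypical variant**
(flag `atypical_cd20_bright`) uses the atypical-CLL immunophenotype
described in hematopathology practice — CD20 raised to the bright level of
normal B cells, brighter surface light chain, moderately dimmer (still
positive) CD200. A CD20-only shift proved too mild to change a trained
network's assignment; the fuller variant phenotype is what reproduces the
low-count network's failure mode (§5).

### Spectral overlap

Fluorescence signals are mixed through a fixed 10×10 diagonal-dominant
spillover matrix (diagonal 0.92, ±1-neighbor 0.03, ±2-neighbor 0.01)
before clipping. The matrix is nonsingular, so the uncompensated
representation carries the same class-separation information as a
compensated one; no compensation is ever applied downstream — the
classifier consumes raw mixed intensities, and written FCS files carry no
$SPILLOVER keyword.

### Aggregates are structural, not a template

Aggregate (doublet) events are composites of two singlet draws from the
case's own singlet mix: pulse areas (FSC-A, SSC-A) and fluorescence add
linearly, while the pulse height FSC-H is that of the taller component —
which is precisely why FSC-A ≫ FSC-H is the doublet signature. FSC-H is
drawn correlated with FSC-A (residual SD 0.03 log10) because both come
from the same pulse; drawing them independently would overstate ratio
noise and blur doublet discrimination that real instruments resolve
nearly exactly.

**Ground-truth consistency rule.** Expert ground truth is produced by
gating, not by knowledge of event composition. A composite whose
area/height ratio falls below the doublet gate (log10 A − log10 H ≤ 0.12)
is indistinguishable from a singlet and is therefore truth-labeled as its
dominant (larger) component's class; only composites above the gate are
labeled `aggregates`. The same principle governs the `unknown` class:
unknown events are smeared low-expression junk (scatter 4.2 ± 0.45,
fluorescence 1.8 ± 0.55 log10), and any draw landing inside a defined
class's 3σ fluorescence box is redrawn — an expert would have gated a
full phenotype match as that population, never as "unknown".

### Case-level variation

Two per-case effects are layered on the templates, reflecting the
difference-from-normal premise of MRD flow: normal populations are
stereotyped across patients, the neoplastic clone is not.

- **Clone phenotype jitter** (`phenotype_jitter_sd`, default 0.08 log10):
  a per-case shift of the CLL template only, emulating inter-patient
  variation in the clone's marker intensities.
- **Run gain drift** (`run_gain_sd`, default 0.03 log10): a per-case,
  per-channel shift shared by all classes, emulating instrument/reagent
  drift between acquisitions.

One deliberate difficulty feature: the granulocyte and monocyte templates
form a partially overlapping continuum (SSC, CD45, CD22, CD38, CD200),
as immature and degranulated forms do in real marrow. This overlap sits
entirely inside the pooled "Other cell categories" report group, so it
cannot distort any MRD quantity, but it raises the irreducible
cross-entropy of the classification problem to just under the 0.08 cost
target — which makes training run the way the clinical system behaves
(sustained training that terminates at ≈ 0.079) instead of terminating
after a trivial number of epochs on an unrealistically easy problem.

### Class prevalences and cohorts

The default class mix approximates a post-therapy specimen: CLL ≈ 5% of
events, T ≈ 10.6%, aggregates ≈ 7.4%, debris ≈ 15.1%, granulocytes ≈ 37%,
monocytes 10%, the rest small. `CaseConfig.cll_fraction_of_wbc` re-derives
the CLL share as a fraction of the white-cell (non-aggregate, non-debris)
portion and rescales the other white-cell classes, so the configured value
is the expected CLL %WBC — the clinically reported scale.

`make_cohort` mixes MRD-negative cases, high-burden positives (CLL %WBC
log-uniform in [0.5%, 30%]) and low-count positives (expected CLL count
uniform in [25, 900] events — below the 1000-event low-count threshold).
A configurable share of the high-burden positives carries the atypical
clone; they are high-burden by construction, so they reach only the
full-cohort network's training stratum. Per-case seeds derive from the
master seed by a fixed counter scheme
(`(master · 1,000,003 + index) mod 2³¹`), so any single case is
reproducible in isolation. Spike-in dilutions draw the spiked count
Binomial(background WBC, target fraction) and resample donor CLL events
with replacement, carrying truth labels over.

## 2. The event classifier (`mrdflow.classifier`)

Architecture: fully connected 13 → 64 → 128 → 64 → 14, ReLU hidden
activations, softmax output, categorical cross-entropy, Adam
(lr 10⁻³, β₁ 0.9, β₂ 0.999), batch size 4096, no dropout and no weight
penalty. The implementation drives scikit-learn's `MLPClassifier` one
epoch at a time via `partial_fit`, which makes the stopping rule and loss
history explicit.

**Stopping rule.** Training stops at the end of the first epoch whose
mean minibatch cross-entropy (the Keras-style running epoch average) falls
below the cost target, default 0.08, or at `max_epochs`. Validation loss
is recorded but never drives stopping. If the target is not reached the
model is returned flagged `target_not_reached` with a warning, not an
error.

**Input scaling.** Events enter as raw uncompensated intensities divided
by one fixed scalar, default 1024 (2¹⁰). This preserves "raw data"
semantics (a single affine scale, no per-channel standardization, no log
or arcsinh transform) while placing typical positive-marker intensities at
order 1–100. Dividing by the full 18-bit range instead (the obvious
alternative, available as `NetworkSpec(scale=None)` which uses the
training-pool maximum) leaves dim-population structure at 10⁻³ feature
scale, and at the fixed stopping rule the rare-class boundaries remain
under-trained: held-out CLL sensitivity drops by roughly a point and the
false-positive floor rises several-fold. The power-of-two constant is
seed- and cohort-independent.

**Two instantiations.** The F-DNN trains on every case; the L-DNN trains
only on cases with < 1000 ground-truth CLL events (MRD-negative cases
qualify). Both share the 80:10:10 event-level train/validation/test split,
seeded and provenance-tracked (case id + in-case event index) so
case-level results can be reassembled from pool predictions. The split is
deliberately at the event level, not the case level: events from one case
appear in more than one pool. This mirrors the intended clinical use
(per-event gating within known specimens) and is documented rather than
"fixed"; the independent-cohort evaluation (§5) is what measures
generalization to unseen cases.

**Determinism.** For a fixed seed and thread count, training and
inference are reproducible; multi-threaded BLAS can perturb results in the
last few ulps through reduction order. Argmax ties break toward the lower
class id in the documented ontology order.

## 3. The hybrid workflow (`mrdflow.workflow`)

1. The F-DNN classifies all events of the case.
2. If its CLL count ≥ 1000 (boundary inclusive: exactly 1000 stays with
   the F-DNN), its labels are final. Otherwise the L-DNN re-classifies
   **all** events and its labels are final.
3. The white-cell denominator is the event count minus predicted
   aggregates and debris; `unknown` counts toward the denominator.
4. MRD-positive ⇔ the deciding network's CLL count ≥ 20. With the
   10⁶-WBC normalization this threshold is the 0.002% analytic
   sensitivity. A zero denominator (pathological all-debris input) yields
   NaN burden with status still computed from the raw count.

No light-chain-ratio rule is applied anywhere in the decision path. The
per-event labels are exported so that a human reviewer can re-gate
near-threshold calls, but the automated result is the deciding network's
count alone.

## 4. Validation statistics (`mrdflow.evaluate`)

- **Per-class metrics** from one-vs-rest TP/TN/FP/FN; when reporting, the
  seven minor classes (basophils/dendritic, blasts, erythroblasts,
  granulocytes, monocytes, NK, unknown) pool into "Other cell
  categories". Ratios with 0/0 denominators propagate as NaN rather than
  0, so empty classes cannot silently inflate a metric.
- **ROC AUC**: rank-based (Mann–Whitney with average ranks on ties),
  computed on the class's softmax probability as the score.
- **Exact binomial CIs**: Clopper–Pearson via beta quantiles; lower bound
  pinned to 0 at k = 0, upper to 1 at k = n. Level fixed at 95%
  throughout; no multiplicity adjustment.
- **Passing–Bablok regression**: the original procedure. All C(n,2)
  pairwise slopes; 0/0 pairs discarded; zero-denominator slopes enter as
  signed infinity; slopes exactly −1 discarded; K counts slopes < −1; the
  slope is the K-shifted median, making the estimator invariant to
  swapping the methods; intercept = median(y − slope·x). Confidence
  bounds use rank indices M₁ = round((N − C)/2), M₂ = N − M₁ + 1 with
  C = z₁₋α/₂ · sqrt(n(n−1)(2n+5)/18); intercept bounds reuse the slope
  bounds. The K-shift index is clamped into range so that pathological
  (predominantly negative-correlation) inputs return the boundary order
  statistic instead of failing; the method's assumptions do not cover
  such inputs, and the clamp only affects them.
- **Dilution error rules**: per comparison row, proportionate percent
  error 100·(DNN − expert)/expert when the expert count ≥ 1000, absolute
  event delta otherwise; the %WBC error is always the absolute
  difference.
- Golden tests pin these implementations to published clinical-table
  values recomputed from their printed count cells, compared at each
  cell's own printed precision (one ulp of the printed digits — a few
  published cells are truncated rather than half-up rounded).

## 5. The synthetic experiments: sizes, and what they show

The test suite and `scripts/acceptance.py` run the pipeline end to end at
deliberately reduced problem sizes, chosen so the full suite completes in
minutes on one CPU while every qualitative behavior of the full-scale
system is exercised:

- development cohort: 20 cases × 50,000 events (≈ 10⁶ events; the
  clinical development cohort was 202 cases × 1.2·10⁶ events), 143/202
  MRD-positive, 60% of positives low-count, 30% of high-burden positives
  atypical;
- independent evaluation cohort: 16 cases (clinically 34);
- dilution study: one donor spiked into a 1.29·10⁶-event background
  (≈ 10⁶ WBC — full clinical scale, since the 20-event threshold only
  makes sense at this denominator) at 0.02% / 0.002% / 0.001%, two
  replicates each.

Under these conditions the trained F-DNN reaches the cost target at a
final loss of ≈ 0.07–0.08 within a handful of epochs (each epoch ≈ 200
Adam steps), held-out CLL AUC exceeds 0.999, one-vs-rest specificity
exceeds 0.999, the hybrid pipeline's case-level counts track truth with a
Passing–Bablok slope CI containing 1, the dilution series recovers the
0.02% level inside its binomial sampling band and straddles the 20-event
limit at 0.001%, and an L-DNN never exposed to the atypical clone misses
most atypical CLL events while the F-DNN classifies > 90% of them
correctly.

**What this does and does not demonstrate.** Passing these experiments
shows the pipeline is correctly assembled: the networks can learn the
class structure the generator encodes, the cascade and thresholds are
wired as specified, and the statistics behave. It does not certify
clinical performance. The generator draws independent lognormal events —
it has no time-dependent fluidics drift, no laser noise, no biexponential
display artifacts, no real fluorochrome spillover values, no
within-population correlation structure beyond the light-chain mixture,
and its class templates are cleaner than patient specimens (the held-out
metrics here are correspondingly higher than any clinical cohort would
give). The "time errors" a clinical pipeline removes upstream are not
modeled; the white-cell denominator therefore uses aggregate/debris
removal only.

## 6. Known limitations

- The classifier is panel-specific (13 fixed channels, matched by name)
  and phenotype-specific; a different antibody/fluorochrome combination
  requires retraining.
- Event-level splitting leaks case identity between training and test
  pools by design (documented above); cross-case claims rest on the
  independent-cohort and dilution experiments.
- The L-DNN's weakness on unseen aberrant phenotypes is reproduced, not
  solved; the hybrid cascade mitigates it only when the F-DNN count stays
  ≥ 1000. Cost-sensitive weighting or oversampling of rare classes is
  intentionally out of scope.
- Checkpoints are Python pickles (versioned and format-tagged); they are
  trusted inputs, not an interchange format.
- With multi-threaded BLAS, bit-exact reproducibility across machines is
  not guaranteed (same-machine, same-thread-count runs are
  deterministic).
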