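# Methods

`fcnets` implements two deep classifiers for functional-connectivity (FC)
matrices — a spectral graph-convolutional network (GCN) with self-attention
pooling, and a conditional auxiliary-classifier GAN (AC-GAN) whose
discriminator is a BrainNetCNN — together with the graph construction,
evaluation protocol and significance tests needed to use them end to end.
This note records the models, the choices made where the design was open,
and what the synthetic cohorts do and do not establish.

## Input model

A subject is a symmetric N×N matrix of Pearson correlations between the
resting-state activity time series of N brain regions (entries in [−1, 1],
unit diagonal), plus a phenotype row: age in years, sex, an optional imaging
site, and a diagnostic label. Phenotypes are encoded as a bounded vector
[age/100] ⧺ one-hot(sex) ⧺ one-hot(site): ages above 100 clamp to 1.0 with a
warning (rejection would exclude valid elderly subjects), one-hot level
order is frozen lexicographically in the cohort manifest, and missing
phenotype values are refused rather than imputed — there is no principled
imputation rule for diagnostic covariates at this scale. The site block is
present only when the cohort has site information.

## Backbone graph

All subjects share one binary graph. The element-wise mean Ā of the
*training* FC matrices (diagonal zeroed) is thresholded: a_ij = 1 iff
Ā_ij > τ, strictly — ties at exactly τ are dropped. The cutoff τ is chosen
at the elbow of the edge-retention curve, the fraction of *positive*
connections surviving each candidate cutoff (negative correlations are
never edges and do not enter the denominator). "Elbow" is operationalised
as the grid point of maximum perpendicular distance to the chord joining
the curve's endpoints, after normalising both axes to [0, 1] so the choice
is unit-independent; ties break toward the smaller τ, and a flat or linear
curve falls back to the smallest grid value with a warning. An explicit τ
can always be supplied instead (published analyses of this architecture
used τ = 0.15 for most cohorts and 0.2 for a single-scanner cohort).

The classifier operator is S = D̃^(−1/2)(I + A)D̃^(−1/2) with
D̃_ii = Σ_j (I + A)_ij. Self-loops guarantee D̃_ii ≥ 1 even for isolated
nodes; S is symmetric, entry-wise nonnegative, and has spectral radius ≤ 1.

## GCN

Node features start as the rows of the subject's own FC matrix, H⁽⁰⁾ = X.
Two spectral convolutions H⁽ˡ⁾ = ReLU(S H⁽ˡ⁻¹⁾ W⁽ˡ⁾) map the feature
dimension N → 25 → 10. One SAGPool layer scores nodes with a one-filter
convolution z = tanh(S H Θ), keeps the k = 10 highest-scoring nodes, scales
their features by their scores, and restricts the adjacency to the kept
rows/columns. The depth is deliberately shallow — deeper message passing
over-smooths node representations on these dense small graphs.

Open details resolved here: top-k ties break by a stable sort toward the
lower node index; kept nodes are returned in ascending original order so
the flattened 10×10-value vector has a stable meaning across subjects;
flattening is row-major over (node, feature); the pooled vector is
projected linearly (no activation) to length 15 and the phenotype encoding
linearly to length 2 before concatenation and a single softmax readout.
Training is Adam at learning rate 0.01 on categorical cross-entropy,
Glorot-uniform initialisation, default 200 epochs at batch size 32 (chosen
for stable convergence at the cohort sizes used here; all exposed in
`GCNConfig`). Optional inverse-frequency class weights are off by default.
When a validation cohort is given, the epoch with the best validation
accuracy supplies the returned parameters.

## AC-GAN

The generator receives a latent vector of total length 50: uniform(−1, 1)
noise filling whatever the condition — one-hot label ⧺ phenotype encoding —
leaves free. A dense layer of width 128 with LeakyReLU(0.2) and a linear
layer map the latent vector to a region-embedding matrix X ∈ R^(N×10)
(the smallest stack that trains stably here; widths exposed in
`GANConfig`), and the output is A = tanh(XXᵀ). The inner product makes
every sample exactly symmetric and tanh bounds entries in (−1, 1);
the diagonal is tanh(‖x_i‖²) ∈ [0, 1), not exactly 1, so the unit-diagonal
rule is waived for generated samples (they are flagged as such on save).

The discriminator is a BrainNetCNN: an edge-to-edge layer (16 cross-shaped
filters: out(i,j) = Σ_k row_w[k]·M(i,k) + Σ_k col_w[k]·M(k,j) + b), an
edge-to-node layer (64 filters aggregating each node's incident edges), and
a node-to-graph layer (128 filters summarising nodes to scalars), each
followed by batch-norm, LeakyReLU(0.2) and dropout 0.5, then dense(64)
(also batch-normed), fusion with a dense(16) projection of the phenotype
vector, dense(32), and two heads: sigmoid validity and softmax class label.
Whether batch-norm follows only the three connectome layers or also the
dense layer is ambiguous in the source architecture; it is applied after
all four.

Losses are the standard AC-GAN composition: the discriminator minimises
validity BCE on real and generated batches plus class cross-entropy on real
samples; the generator minimises validity BCE towards "real" plus class
cross-entropy towards its conditioned label. Applying the class loss to
generated samples on the discriminator side (the semi-supervised variant)
is available behind `class_loss_on_fake_for_d`. Conditioning pairs
(label, phenotype) are resampled from the empirical training distribution,
so the discriminator always sees coherent (matrix, phenotype) pairs. Both
networks use Adam(lr = 1e−4, β₁ = 0.5), alternating one step each per
batch (batch 16). Model selection with a validation cohort uses class
accuracy, breaking ties toward validity accuracy nearest 0.5 (an
equilibrium discriminator). The same backbone trained with only the class
head and plain cross-entropy is the standalone BrainNetCNN baseline.

All networks run on a small in-package reverse-mode autodiff engine over
numpy (`fcnets.autodiff`); at N ≤ 200 regions and desk-scale cohorts the
dense linear algebra involved is comfortably within numpy's reach, and
every layer primitive is verified against explicit loop oracles in the
test suite.

## Evaluation protocol and statistics

10% of subjects are held out for testing (stratified by default; a flag
disables it), the rest is split by stratified 5-fold cross-validation. Each
model trains once per fold; the fold with the best validation accuracy
supplies the parameters evaluated once on the test set. Metrics: accuracy
and one-vs-rest macro precision, recall/sensitivity, specificity, F1 and
ROC AUC. Per-class metrics with zero denominators are excluded from the
macro mean with a logged note rather than silently zeroed. Binary problems
report the standard single-positive-class definitions with the patient
class positive, matching the sensitivity/specificity orientation.

Two tests accompany the metrics. (1) An exact one-sided binomial test of
the test-set success count against chance — p₀ = 0.5 for binary problems
and 1/n_classes for multiclass (the natural generalisation; p₀ is a
parameter). (2) A one-sided Wilcoxon rank-sum test comparing two models'
fold accuracies, with the exact null distribution computed by enumeration
of rank assignments (mid-ranks for ties) for combined n ≤ 12 and a
tie-corrected normal approximation above. With 5 + 5 fold accuracies the
exact path always applies. Significance tests are run on the held-out test
set predictions (whether published analyses pooled CV predictions instead
is not documented; the held-out choice is the stricter one).

## Synthetic cohorts

Real FC matrices are sample correlations, so the generator simulates the
same estimator: each class has a population correlation matrix; each
subject's matrix adds symmetric Gaussian jitter (sd 0.05 by default) to its
class matrix, is repaired to a valid correlation matrix (eigenvalue
clipping at 1e−6, rescale to unit diagonal), and T = 150 latent Gaussian
time points drawn from it yield the subject's sample Pearson matrix.
Sampling noise therefore scales as ≈(1 − r²)/√T, as in real data, which is
what makes thresholding and classification behave realistically — adding
noise directly to correlations would not reproduce this.

The population structure: a backbone of 30% of edges at correlation ≈ 0.3
(remaining edges near 0), and for each non-reference class a shift of
Δr = 0.4 planted on a random 5% of edges (sign flipped when a shift would
leave (−1, 1); an infeasible Δr is rejected before sampling). Defaults —
N = 20 regions, two balanced classes of 50, T = 150 — are the study
conditions used by the tests and the acceptance script. Phenotype
distributions are class-independent by default (age ~ Normal(30, 10)
truncated to [5, 90], sex Bernoulli(0.5), optional uniform site), so a
zero effect size yields a genuine null cohort: any class-specific
phenotype signal must be opted into explicitly.

What the synthetic cohorts do not emulate: site/scanner batch effects,
motion artifacts, hemodynamic filtering, heavy-tailed or negatively-skewed
correlation distributions, and class differences expressed in variance
rather than mean. Passing tests therefore establish that the
implementations are correct and can recover mean-shift signal at realistic
sampling noise — not that the architectures reach any particular accuracy
on clinical data.

## Problem sizes and numerical choices

The test suite and acceptance script train at N = 20 regions with
80-subject training sets, with 200 epochs for the GCN. GAN-family training
lengths vary by what the check needs: 60 epochs suffice for the
discriminator's classification accuracy (signal-recovery and null checks);
the scarce-data GAN-vs-BrainNetCNN comparison uses 150 epochs with
validation-based model selection for both models (12 train + 3 validation
subjects per class out of the 15 available — selection by validation
accuracy is part of the evaluation protocol, and for adversarially trained
discriminators it matters: the end-of-training state is often a poor point
of the training dynamics); the generator-conditioning probe uses the full
300-epoch default, since the per-class structure of generated samples is
the slowest property to emerge.
The exact binomial null-calibration simulation uses 200 replicates with a
30-subject test set, where the discrete test's nominal size is 4.94%, as
close to the 5% level as the discreteness allows; a fast logistic-regression
classifier on vectorised upper-triangle features stands in for the (much
slower) deep models there, since the property under test is the
calibration of the *test*, not of any particular classifier.

Determinism: every stochastic operation takes an explicit seed and uses an
isolated `numpy` generator; the CLI fans a single global seed out to named
stage seeds by hashing, so adding a pipeline stage never perturbs the draws
of earlier stages. Training, sampling and the full CLI pipeline are
bit-reproducible under a fixed seed.

Known limitations: no GPU path (deliberate — the models are small); binary
backbone graphs only (no weighted or directed variants); the GAN objective
is the plain AC-GAN composition without Wasserstein or spectral-norm
stabilisation, adequate at these problem sizes but not tuned for
N = 200-region cohorts with hundreds of subjects; batch-norm statistics
make the discriminator's training-mode forward depend on batch composition
(eval mode uses running averages and is batch-independent).
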