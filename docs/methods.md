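# Methods

## Base learner

Every scoring function in the package is built from the same base learner: a
fully connected feed-forward network with one hidden layer.  For a descriptor
vector x (restricted to the learner's feature subset p and min-max scaled),

    yhat = w_{0,o} + sum_{h=1..H} w_{h,o} * S( w_{0,h} + sum_i w_{i,h} * x_i ),

with logistic hidden units S(u) = e^u / (1 + e^u) and a linear output neuron.
Bias terms are absorbed by the convention x_0 = 1 at the input layer and
S(.) = 1 for h = 0 at the hidden layer, so a network declared with
`hidden=20` has 19 sigmoid units plus the constant unit.  Weights minimize

    E = sum_n (y_n - yhat_n)^2 + lambda * sum_{all weights} w^2,

the squared-error criterion with a quadratic weight-decay penalty over both
layers including biases.  The penalty keeps hidden units out of saturation;
inputs are scaled to [0, 1] on the training rows so one lambda is meaningful
across descriptors of different magnitudes.

**Optimization.**  The criterion is minimized full-batch with L-BFGS using
analytic gradients (plain backpropagation of the squared error plus the
2*lambda*w decay term).  `epochs` caps the optimizer iterations — the
historical term is kept because the reference protocol counts "training
epochs" — and training stops early once E < `abstol`.  Initial weights are
uniform in ±`init_range`.  L-BFGS accepts only descent steps, so E never
increases across accepted iterates; runs are bit-reproducible from
(data, subset, config) because initialization is the only stochastic step.

**Defaults** (the reference protocol's tuned values): 3000 epochs,
lambda = 0.005, abstol = 1e-4, init range 0.7, H+1 = 20 hidden neurons,
ensemble size L = 3000, feature-subset size |p| = 10 (3 when only the
six-column X block is in play), shrinkage nu = 0.001, 10-fold
cross-validation.

**Numerical choices.**  A constant training column gets scaling range 1, so
its scaled value is exactly 0 rather than dividing by zero.  Test-time
inputs reuse the training min/range *without clipping*: extreme complexes
extrapolate, because clipping would silently collapse their ranking.  The
target variable is not scaled; the linear output neuron covers its range.
Non-finite objectives abort with a diagnostic rather than propagating NaNs.

## Bagged ensemble (BgN-Score)

Each of the L members trains on a bootstrap resample (with replacement, size
N — classical bagging) of the training complexes, described by its own
random subset of |p| descriptors drawn uniformly without replacement (the
random-subspace device borrowed from Random Forests).  The ensemble
prediction is the unweighted mean of the member outputs.  Rows absent from a
member's bootstrap — on average (1 - 1/N)^N ≈ 34% of them — are that
member's out-of-bag (OOB) complexes; averaging each row's predictions over
the members that did not see it yields validation predictions without a
held-out split.  OOB errors are aggregated per complex (each row's OOB
predictions are averaged first, then scored).

Members that converge poorly are *kept*: imperfect weight tuning decorrelates
members and is part of the ensemble's diversity.  Only members with
non-finite weights are retrained with a bumped seed (at most three times).

## Boosted ensemble (BsN-Score)

Stage 1 trains on all N complexes with a random feature subset; the working
residuals start at R^1 = Y - nu*yhat_1.  Each later stage l bootstraps N
rows, trains a network on the sampled rows' *current* residuals (duplicated
rows carry duplicated residual targets), predicts on all N rows, and updates
R^l = R^{l-1} - nu*yhat_l.  The prediction is the nu-shrunk sum over all
stages.  Three consequences of this exact formulation are worth flagging:

* every stage is shrunk, including the first, so the model's total weight is
  L*nu.  With nu = 0.001 the matching L is 3000; a short model with small nu
  systematically under-predicts in absolute terms (correlation and rank
  metrics are unaffected).  This is a property of the algorithm as specified,
  deliberately not "fixed" with an intercept or unshrunk first stage;
* no base score / intercept term exists;
* only the squared-error loss is supported.

Each stage refits its input scaler on its own bootstrap sample so members
stay self-contained.  The residual sum of squares after every stage is
recorded (`residual_trace`) and satisfies the identity
R^L = Y - sum_l nu*yhat_l to floating-point accuracy, which the tests assert
at 1e-10.

Hyperparameters for the boosted and single-network models are selected by
k-fold cross-validation (shuffle indices with the given seed, deal
round-robin, so fold sizes differ by at most one); ties prefer fewer stages,
then smaller subsets.  Bagged models are selected by OOB error instead.
Model selection never reads the test partition.

## Scoring-power statistics

R_p is Pearson's correlation between predicted and measured affinities; R_s
is Spearman's rank correlation computed as Pearson on average ranks, which
reproduces the classical 1 - 6*sum(d_i^2)/(n(n^2-1)) formula exactly in the
absence of ties and degrades gracefully with them.  SD is the standard
deviation of errors about the least-squares line of *measured on predicted*
(Y = b0 + b1*Yhat) with an n-2 denominator, in -log K units; RMSE is the
raw root-mean-square error.  SD <= RMSE does *not* hold in general (SD is
computed about a fitted line), and SD is invariant under positive affine
rescaling of the predictions while RMSE is not.  Degenerate inputs (constant
vectors, all ties) raise rather than return NaN so pipelines fail loudly.

## Synthetic benchmark generator

The generator emulates the *shape* of a curated affinity benchmark: n
complexes (default 1300) in F protein families (default 65), 86 descriptors
in four blocks (X:6, A:30, R:36, G:14), affinities on the -log K scale, and
a family-stratified core holdout (default 15%, giving the 1105/195 split
with exactly 3 core complexes per family).

Features: each (family, block) pair draws a latent offset (scale 0.5); a
complex's block factor is its family offset plus complex noise, standardized;
feature j of a block is sqrt(rho)*z_block + sqrt(1-rho)*e_j, giving
within-block correlation `redundancy_rho` (default 0.6) and unit variance.
This mirrors real descriptor tables, where many redundant columns measure a
few underlying interaction quantities — and it is exactly what makes
random-subspace ensembles viable, since any handful of a block's columns
estimates that block's factor.

Ground truth: a smooth nonlinear function of the four block summaries
s_b(x) (block column means) — linear terms, two squared terms, two
cross-block products, two saturating sigmoids — around a baseline of
6 -log K units, with signal weighted toward the column-rich A and R blocks.
Observed affinity adds N(0, noise_sd^2) noise; the default
noise_sd = 0.8 -log K puts attainable Pearson correlations in the
high-0.8 regime typical of strong scoring functions.  The curvature and
interaction terms keep purely linear baselines beatable.

What the generator does *not* emulate: realistic descriptor marginals
(counts, energies), heavy-tailed experimental error, assay heterogeneity, or
any 3-D structure.  Tests passing on these tables validate the learners'
machinery (resampling, aggregation, residual bookkeeping, model selection),
not performance on real complexes.

**A note on recovery ceilings.**  With noise at 0.8x the signal spread the
best possible test Pearson correlation is 1/sqrt(1.64) ≈ 0.781, and a mean
of 0.75 demands recovering 96% of the signal correlation.  Measured
noiseless recovery at desk scale (L=100 members, |p|=10 of 86 columns) is
about 0.95 for bagging and 0.96 for boosting, so under that noise level the
ensembles operate at their structural limit: replicate means land in the
0.72–0.77 band depending on the seed draw, while the ensemble-vs-single-
network ordering is stable (the single network trails by ~0.12 and loses in
essentially every replicate).

## Contact-count descriptors

The R block is computed from structures as intermolecular element-pair
occurrence counts: for each (protein element, ligand element) pair in the
alphabets {C,N,O,S} x {C,N,O,F,P,S,Cl,Br,I}, the number of atom pairs within
a cutoff (default 12 Å, boundary inclusive, both configurable).  These
defaults are this package's reconstruction of the common contact-count
recipe, stamped into output metadata, not an externally fixed standard.
Protein atoms come from fixed-column PDB ATOM/HETATM records — waters
excluded, altLoc blank/'A' kept, all chains, element from columns 77-78 with
a column-position-aware atom-name fallback — and ligand atoms from V2000
SDF via RDKit with hydrogens kept (elements outside the alphabets simply
never match).  Counting uses a KD-tree per ligand element; the tests require
exact agreement with an all-pairs double loop, including at the closed
boundary.

## Desk-scale experiment sizes

The packaged experiments (`ennscore.experiments`) run the full protocol at
reduced size so a study completes in minutes on one core: 600/200
train/test complexes, ensembles of L=100 networks with a 150-iteration
training budget, nu=0.01 paired with the shorter L, 10 seed replicates.
Raising the budget to 400 iterations was checked and slightly *hurts* test
correlation (the members start fitting noise), so 150 is kept.  The
constant-target boosting fixture uses 25 rows and 200 stages; the variance-
reduction study uses 20 seed replicates at L=1 vs L=50.

## Known limitations

Single hidden layer only; squared-error loss only; no parallel training
(any execution order must reproduce the seed-deterministic result — the
contract is determinism, not scheduling); no significance tests or bootstrap
confidence intervals on the reported statistics; the feature table contract
is a plain CSV with prefix-tagged columns, not any external index format.
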