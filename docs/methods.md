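# Methods

`visparc` re-creates, as a tested pipeline on synthetic data, a
functional-parcellation analysis of mouse visual cortex: given per-pixel
(wide-field) or per-neuron (two-photon) dF/F calcium time series and
retinotopically derived area labels for the six core visual areas (V1, LM,
AL, RL, AM, PM), it asks whether each area's activity carries a signature
that identifies the area, using supervised classification and a
semi-supervised region-growing parcellation.

## Synthetic data model

Real recordings of this kind are large and not freely redistributable, so
the package ships a generator that reproduces the statistical structure the
analyses rely on, with every condition controlled.

**Geometry.** An elliptical imaging window on an `n_rows x n_cols` raster is
partitioned into six 4-connected areas by competitive wavefront growth from
six seeded points (a multi-label Dijkstra through each region's own
territory, which guarantees contiguity). The V1 seed expands at sqrt(2) the
speed of the others, giving it roughly a 2x pixel budget; V1 always ends at
least as large as any other area, which is what makes the size-biased
chance level interesting. Pixels outside the ellipse are background
(label 0) and are excluded from every analysis.

**Signals.** Each pixel's trace is an additive Gaussian model (units:
dF/F; all latents white in time):

    x_p(t) = sigma_global * g(t) + sigma_area * a_{area(p)}(t)
             + k_{area(p), stim(t)}(t - onset)        (during trial windows)
             + sigma_noise * eps_p(t)

`g` is shared by every pixel, `a_k` by all pixels of area `k`, and the
stimulus kernels `k_{area,stim}` (amplitude `kernel_amplitude`, default 1)
are drawn once per simulation, so trial averaging raises the
signal-to-noise ratio exactly as repeated presentations do in real data.
The noise field is optionally Gaussian-smoothed across space
(`spatial_smooth_px`, default 1 px) to mimic the optical blur that
correlates neighboring wide-field pixels; smoothing is applied after
amplitude scaling and therefore shrinks the noise variance. With no
smoothing, the pairwise Pearson correlations have closed forms --
intra-area (sigma_a^2 + sigma_g^2) / total and inter-area
sigma_g^2 / total -- which the tests verify at T = 20 000 frames.

**Trials.** A block design: every stimulus appears once per block in a
random order, repeated `n_trials` times (defaults: 8 stimuli x 10 trials,
2 s stimuli, 2 s blanks, 10 Hz), followed by an untrialed resting-state
segment (default 120 s). Two-photon mode uses the same latent model with no
spatial structure and exact per-area unit counts (e.g. the unbalanced
counts of the public Allen Brain Observatory sessions, which serve as the
worked example for the size-biased chance level).

**What the generator does not emulate** -- and hence what passing tests do
not show about real data: within-area heterogeneity (every pixel of an area
has the same expected response, so trial-averaged features form six
near-atomic clusters), hemodynamic/optics modeling beyond the blur kernel,
indicator kinetics, eye movements, behavioral state, and non-stationarity
of resting activity. Three visible consequences, all verified rather than
hidden:

* the label-shuffle control does not land at the ~1/6 level reported for
  real data: with six tight clusters a shuffled-label classifier assigns
  whole clusters to arbitrary labels, so generative classifiers are noisy
  around or below chance and discriminative ones collapse to the majority
  class (~ the V1 pixel share, ~36%); the corresponding acceptance check
  is left failing rather than re-tuned;
* the resting-state condition is unrealistically informative (stationary
  latents with no transients), so resting accuracy saturates quickly and
  the real-data ordering "trial-averaged > single-trial > short resting"
  only holds for its first comparison here;
* the inter-area correlation of LDA features is negative (see below).

## Feature front end

Responses enter as units x timepoints matrices; units are samples and
timepoints are variables. Traces are z-scored per unit (mean 0, SD 1 over
time) before PCA, which removes trivially classifiable brightness offsets
so classification reflects response shape; being per-row, z-scoring cannot
leak statistics between training and test units.

**PCA** eigendecomposes the 1/n-normalized covariance over the time axis
(expectation form, not the 1/(n-1) sample convention -- tests match this).
The default keeps the smallest K explaining 95% of variance, capped at 50.
Implementation routes: exact `eigh` on the T x T covariance when T is
moderate, the Gram-matrix trick when units are fewer, and a seeded
randomized SVD when both sides are large (deterministic; eigenvalue mass is
then referenced against the exactly computed total variance).

**LDA** maximizes the Fisher ratio of the 1/C-normalized between-area
scatter to the *total* covariance of the PCA features (not the within-class
scatter), solving the generalized symmetric eigenproblem; at most C-1
directions are kept, each unit-norm with its largest-magnitude entry
positive (a fixed sign convention keeps runs reproducible). A ridge
tau = 1e-6 * trace(Sigma)/K is added when the covariance's condition number
exceeds 1e8.

A note on correlations in the LDA domain: LDA features are centred on the
training grand mean, so the size-weighted class-mean vectors sum to ~0 and
the average cross-class similarity is necessarily negative once classes
separate well. `correlation_analysis` therefore flags the intra/inter
ratio as undefined when the inter-area mean is <= 0 and reports it as +inf
-- a nonpositive inter-area correlation with positive intra-area
correlation is maximal contrast, which is how the "LDA improves the ratio"
comparison is evaluated.

## Classifiers

Four supervised models share a fit/predict contract; all ties break to the
lowest area code.

* **Unimodal Bayes** -- per-area Gaussian, MLE mean and 1/n covariance,
  equal priors (the Bayes rule reduces to maximum likelihood). Covariances
  are floored by clipping eigenvalues at
  max(1e-6 * mean eigenvalue, 1e-10).
* **GMM** -- one mixture per area, EM from a seeded k-means start,
  convergence at relative tolerance 1e-6 or 200 iterations, with the same
  flooring. Default 4 components, but a capacity guard caps the per-area
  count at n_area // (2 d): a full-covariance component in d dimensions
  fitted to fewer samples collapses onto the floor and assigns
  catastrophically low likelihood to its own class's held-out data.
* **SVM** -- one-against-one machines (15 for 6 classes) via LIBSVM,
  RBF kernel with gamma = 1/(N var(F)), C = 1 by default; prediction
  recomputes the pairwise votes from the decision values so the
  lowest-code tie-break is exact.
* **ANN** -- one hidden layer of 30 tanh units, softmax output,
  cross-entropy loss, mini-batch SGD (lr 0.01, batch 32, 500 epochs).

## Semi-supervised parcellation

The only supervision is one labeled grid cell per area. Steps: PCA-only
features for every in-map pixel; a universal background model (UBM; a
64-component diagonal-covariance mixture, EM-trained on all pixels without
labels); a square grid partition (edge cells under a quarter of the cell
area are folded into their best-connected neighbor); seeding of the cell at
each area's interior pole (distance-transform argmax -- centroids of
concave areas can fall outside them); then iterative region growing.

Cluster-specific models come from means-only MAP adaptation of the UBM:
component k moves to alpha_k E_k + (1 - alpha_k) mu_k with
alpha_k = n_k / (n_k + r), occupancy n_k from the UBM responsibilities and
relevance factor r = 16 (the standard value in the UBM adaptation
literature). The merge score between cells a and b,

    S(a,b) = log p(D | lam) - log p(D_a | lam_a) - log p(D_b | lam_b),

with each model adapted to its own data and D the union, is a modified
Bayesian information criterion: the likelihood gain from modeling the two
cells jointly, with the usual penalty term replaced by an adaptive
threshold -- each iteration merges the top x% of (labeled cell, unlabeled
neighbor) scores, x falling linearly from 80 to 20 as the labeled cell
fraction grows; at least one merge per iteration guarantees termination,
and a contested cell joins the higher-scoring region. The joint data are
put in a canonical order before adaptation so S is exactly symmetric, and
S = 0 exactly under infinite relevance (log-likelihood additivity), which
the tests assert. Finally, a supervised GMM classifier trained on a 5%
sample per grown cluster reclassifies every pixel, smoothing the blocky
cell boundaries.

Two regime conditions matter and are documented because they bound what
the method can do:

* the merge score ranks same-distribution pairs above separated pairs only
  while UBM components are *shared* between the compared cells'
  distributions; on data whose areas form atomic clusters, any UBM rich
  enough to memorize each cluster makes cross-area pooling costless and
  the ranking uninformative (the growth then relies on seeding and
  geometry, which is sufficient on the default sheet);
* the grid must be fine enough that region frontiers reach area boundaries
  only after the adaptive threshold has tightened; with ~9 cells per area
  the initial 80% merge wave swallows cross-boundary cells, so the default
  cell size is 4 px on the 64 x 64 sheet (~35 cells per area, 16 pixels
  per cell -- still ample for means-only adaptation).

Under these defaults the zero-noise sheet is parcellated exactly (100%),
the default noisy sheet reaches ~97-99%, and two UBMs trained with
different seeds agree on ~97% of pixels.

## Evaluation protocols

Per-area random splits (5% training for wide-field, 50% for two-photon),
PCA+LDA and classifier refit per repeat on training units only, rank-1
accuracy on the rest, mean +/- SD over 5 repeats (3 UBM initializations on
the semi-supervised side). Controls: a radius-restricted mode confining
training pixels to the central fraction of each area's radius (radius =
within-area distance-transform maximum), and a shuffle control that
permutes training labels while keeping test labels intact -- the whole
training pipeline, LDA included, sees the shuffled labels. Chance levels:
unbiased 100/C % (rounded to 2 decimals) and size-biased
100 * sum p_i^2 % (truncated -- not rounded -- to 1 decimal, matching how
such values are conventionally printed; averages across sessions are
computed on untruncated values and truncated once). The duration sweep
truncates the feature time base of trial-averaged, single-trial, and
resting responses to a grid of durations and re-runs the supervised
protocol; the resting trend is summarized as a Spearman rank correlation,
defined as 0 when accuracy is flat (saturated) across durations.

## Problem sizes and numerical choices

The default study conditions -- a 64 x 64 sheet (~3 100 in-map pixels),
8 stimuli x 10 trials at 10 Hz, 120 s resting -- keep every analysis,
including the full acceptance recomputation, within a couple of minutes on
one CPU while preserving the regimes of interest (dominant V1, intra >
inter correlation, trial-averaging gains). Degenerate inputs are handled
explicitly: all-zero simulations, constant traces (excluded from
correlations, zeroed by the z-score), zero covariance (error), empty cells
(error), k-means components that lose all mass (dropped), and non-PD
covariance estimates (eigenvalue flooring). Every stochastic step takes an
explicit seed and all randomness flows through `numpy.random.default_rng`.

## Known limitations

The generator's lack of within-area heterogeneity makes supervised
classification easier, and the shuffle control harder, than on real data
(see above); the merge-score ranking is uninformative in the atomic-cluster
regime; resting-state windows are unrealistically stationary; and the
wide-field per-area pixel ratio is a free parameter of the geometry, so
size-biased chance values for wide-field data are properties of the
generated map rather than of any real cortex.
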