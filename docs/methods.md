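# Methods

## Model

A genetic network over N genes is described by one ordinary differential
equation per gene,

    dX_n/dt = F_n(X_{-n}) - beta_n X_n,        n = 1..N,

where X_m is the expression level of gene m, X_{-n} collects every element
except gene n (including any stimulus indicator elements), F_n is an
arbitrary regulation function and beta_n > 0 is a first-order degradation
rate. Inference decomposes into N independent per-gene subproblems: find an
approximation F_hat_n and a value beta_n* consistent with the data, then
score every candidate regulator m of gene n by how much F_hat_n relies on
column m.

### Per-gene regression and the decay-rate search

For a candidate beta_n the regression targets are

    y_tk = dX_n/dt|t_k + beta_n X_n|t_k      (time-series measurements)
    y_sk = beta_n X_n|s_k                    (steady-state measurements,
                                              whose derivative is zero),

so that a perfect F_hat reproduces y from X_{-n}. Time derivatives are
estimated by local linear regression (below); every measurement carries a
weight (w_k^T for time-series rows, default 1.0; w_k^S for static rows,
default 1.1), and externally supplied discounted weights can be loaded from
a one-column TSV. F_hat_n is a forest of weighted regression trees fitted to
these pairs, and beta_n is chosen by minimizing

    S_n(beta) = beta^e * sum_k w_k [y_k - F_hat_n(x_k)]^2,   e = -1,

by golden-section search on log beta over [-10, 5] with tolerance 0.01.
Two numerical choices matter here:

* **Out-of-bag residuals.** In-sample residuals of a deep forest are close
  to zero for *any* beta, so S_n would carry no information; residuals are
  therefore taken against out-of-bag predictions (rows in-bag in every tree
  fall back to the all-tree mean and are flagged).
* **The beta^-1 factor** gives S_n an interior minimum: held-out error grows
  roughly like beta^2 for large beta (so S_n grows ~beta), while the 1/beta
  factor diverges as beta -> 0 where the targets degenerate to the bare
  derivatives. The exponent is configurable (`beta_exponent` in {-2, -1, +1}).
* **Determinism.** Every objective evaluation during the search reuses one
  fixed seed, so the searched function is a deterministic function of beta;
  a cheaper search forest (`search_n_tree`) may be used before the full
  final refit. Golden-section assumes unimodality; S_n(beta) is piecewise
  smooth in beta with small discontinuities where tree structures change,
  so the returned beta* is a local minimizer of that deterministic surface.

### Weighted trees and importance

Trees minimize the weighted sum of squared errors. For a node nu with
allocated rows k (weights travel with rows; bootstrap duplicates count
twice):

    N_w(nu)   = sum_k w_k
    ybar_w(nu)= sum_k w_k y_k / N_w(nu)
    Sq_w(nu)  = sum_k w_k (y_k - ybar_w(nu))^2

and the split gain is the decrease in weighted SSE,

    I(nu) = Sq_w(nu) - Sq_w(nu_L) - Sq_w(nu_R)  >= 0.

A `literal` importance mode multiplies each Sq_w by its N_w inside the gain;
it is kept as a switch because it breaks the telescoping property below.
Deterministic splits scan midpoints between consecutive distinct values of
`n_test` sampled candidate inputs. Exact gain ties (routine at small nodes,
where any cut separating two rows scores the same) are broken by reservoir
sampling from the tree's seeded stream — a fixed lowest-index rule would
systematically favour low-index columns, which measurably biases the
shadow-feature relevance test whose premise is that original and shadow
columns have even chances. Four variants share this machinery:

* `rf` — classic random forest (bootstrap on, candidate subsampling);
* `rf_paired` — candidate sampling in original/shadow pairs (used by the
  feature-selection stage, below);
* `extra` — Extra-Trees: one uniformly random cut per candidate, best gain
  wins; no bootstrap;
* `vr` — VR-Trees: with probability `vr_alpha` the deterministic best split
  over all inputs, otherwise a uniformly random (variable, cut) pair; no
  bootstrap.

Growth stops at purity, at fewer than `min_node` (2) rows, or at height
`h_max` (32). All randomness derives from per-tree seeds spawned from the
master seed; identical seeds give identical forests.

The confidence that element m regulates gene n is the normalized importance
of column m in the final forest at beta*:

    C_{n,m} = (1/N_tree) * sum_i [ sum_{nu in V_i(m)} I(nu) ] / Sq_w(root_i),

where V_i(m) are the nodes of tree i splitting on m. Summing gains down a
tree telescopes to Sq_w(root) minus the summed leaf dispersions, so each
tree's contribution lies in [0, 1] and therefore sum_m C_{n,m} <= 1 exactly.
For trees grown on the full sample, Sq_w(root) equals the global weighted
dispersion Sq_w0 of the targets, recovering the single-denominator form;
for bootstrapped trees the per-tree denominator is preferred precisely
because the bootstrap root dispersion fluctuates around Sq_w0 and a global
denominator would let the bound fail by O(1/K) noise. Constant-target
subproblems (Sq_w0 = 0) yield an all-zero row with a logged warning.

### Derivative estimation

Noisy series are smoothed per gene per experiment by local linear
regression: at each time t_k a weighted straight line is fitted over the
`ceil(span * K)` nearest points (default span 0.3, truncated at series
ends), with tricube weights on distance normalized by the distance to the
(r+1)-th nearest point — the conventional cutoff-at-the-boundary tricube
would zero out both neighbours of a symmetric interior window and collapse
the fit. The fitted intercept is the denoised level, the slope the
derivative. Two-point windows fall back to uniform weights; the kernel is
configurable (`tricube` | `uniform`). The bandwidth is a documented default,
not a published value.

### Permutation-copy feature selection

For gene n's training matrix (at beta*), each input column i is paired with
a shadow column holding an independently permuted copy of its values. One
ensemble is trained on the doubled matrix (with the measurement weights),
and input i scores a win when its total importance strictly exceeds its
shadow's (ties count as losses). Over `n_rf` independent replicates the win
count C_i is Binomial(n_rf, 1/2) under the null that input i is irrelevant
(input and shadow are then exchangeable), and i is declared irrelevant when

    z_i = (C_i - n_rf/2) / sqrt(n_rf/4)  <=  Phi^-1(alpha_s),

i.e. when it loses to its own shadow significantly often (alpha_s = 0.01:
z <= -2.3263, or C_i <= 38 of 100). Three backends run the same test:

* the paired random forest (`rf_paired`, candidate count 2*ceil(M/3)), whose
  paired sampling gives original and shadow even chances of being selected
  for splitting;
* Extra-Trees and VR-Trees (alpha 0.5) unmodified over all 2M columns.

The binomial null should be read *conditionally*: given a win probability
of 1/2, the z-test has level alpha_s. Marginally — over draws of the
dataset — an irrelevant input's per-replicate win probability is the
quantile of its one realized column within the permutation distribution of
importances, which spreads the win counts far beyond binomial (measured
sd ~ 19-20 at n_rf = 100, versus 5 for the binomial, stable across sample
sizes). An exactly-irrelevant input is therefore removed with probability
of order 0.1-0.4 rather than ~alpha_s, which is the poor specificity the
method's originators themselves report ("erroneously concluded to be
relevant with a probability of about 0.5"); combining three backends and
the rarity of exactly-irrelevant inputs in real, correlated expression data
keep observed removal counts modest in practice.

Each backend also emits a per-input confidence D_i. The default orientation
is the win rate D_i = C_i / n_rf (large = well supported); the complement
1 - C_i/n_rf is available as `fs_confidence="printed"`. The win-rate
orientation is the one consistent with using min{D} across backends as the
*worst* (most conservative) estimate in the mixing step, and with the
observed behaviour that feature-selection-only rankings carry real signal.

### The combined method

Per gene n: drop gene n's own knockout/knockdown statics, fit the
subproblem, compute the confidence row, then run the three backends on the
same beta*-training data and adjust:

* if any backend declares m irrelevant, set C_{n,m} = 0 ("no regulation");
* otherwise C_{n,m} <- p C_{n,m} + (1 - p) min(D_rf, D_et, D_vt), with
  mixing parameter p = 0.9 by default (p = 1 keeps the plain confidences,
  changed only by zeroing; feature selection disabled entirely reproduces
  the plain random-forest-based method bit-for-bit under the same seed).

Indicator elements (stimulus/perturbation columns, optionally decaying as
base^(t/scale), defaults 0.9 and 48 minutes) act as candidate regulators
but never as targets, and indicator-sourced pairs are excluded from
evaluation, not from inference.

### Evaluation

Predictions at threshold t are pairs with confidence > t; recall and
precision follow from TP/FP/FN against a gold-standard edge set, with
self-pairs and indicator-sourced pairs excluded. The recall-precision curve
takes one point per distinct positive confidence (ties enter together);
zero-confidence pairs are never predicted, truncating achievable recall.
AURPC integrates precision over recall by trapezoid across the
recall-increasing points with the leading segment extended horizontally
from (0, P_first); a Davis-Goadrich interpolation mode is available. A
random ranking scores close to the gold edge density, with a small upward
finite-list bias (precision is convex in the counts).

## Synthetic data

The simulator draws networks with chosen gene and edge counts: strengths
|a| ~ U(0.3, 1.0) (60% activating), basal rates b ~ U(0.5, 1.5), decays
beta ~ U(0.5, 1.5), with rejection of parameter sets lacking a finite
nonnegative steady state. Regulation is rectified-linear by default
(F_n = max(0, b_n + sum a_nm X_m)) or saturating (b_n * sigma(sum a X)).
Trajectories use fixed-step RK4 (default step 0.01, observations every 0.5
time units, 21 points); static data are the wild-type steady state plus
every single-gene knockout (clamped to exactly 0) and knockdown (basal rate
halved). Noise is additive Gaussian on observations only (default sd 0.05,
floored at 0) — simpler than the stochastic internal/external noise of the
DREAM generators, so passing tests demonstrate correct mechanics and
recoverability under observational noise, not robustness to process noise,
topology realism, or unmodelled measurement bias.

## Desk-scale study conditions

Full-scale runs of the published setting (100 genes, 1000-tree forests,
feature selection with 100 replicates of 100 trees per gene) cost tens of
CPU-minutes per gene; this package's validation suite instead runs a
desk-scale protocol chosen once as its own study condition:

* networks: 10 genes / 20 edges, linear, observation noise 0.05;
* data: 10 experiments x 21 time points plus the full wild-type/KO/KD
  static set (231 training rows per subproblem);
* inference: 200-tree forests (100-tree search forest), log-beta in
  [-10, 5], tolerance 0.01;
* feature selection: 50 replicates of 25 trees per backend, alpha_s = 0.01;
* mixing p = 0.9; 10 trials = 5 networks x 2 run seeds.

The null calibration of the relevance test keeps the recommended 100
replicates of 100 trees (50 runs x 20 pure-noise inputs = 1000
input-trials). Note that a 20-edge network over 10 genes has candidate-pair
density 20/90 ~ 0.22 — an order of magnitude denser than the published
benchmark networks — so removals strike true regulations far more often at
desk scale, and improvement margins from removal are correspondingly
noisier.

## Known limitations

* S_n is evaluated with out-of-bag residuals; whether the original
  implementation does the same is not documented. In-sample residuals would
  make the beta search uninformative.
* The objective is exactly invariant to measurement (row) order only for
  full-sample trees; bootstrap resampling is positional, so bootstrapped
  objectives are order-invariant in distribution only.
* The exact "slightly modified" paired training of the feature-selection
  forest follows the paired-candidate reconstruction described above; the
  cited original is not public in detail.
* No refit on the reduced variable set after removal; no joint optimization
  across genes; no normalization or imputation of input data.
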