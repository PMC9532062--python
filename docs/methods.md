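# Methods

## Problem setting

The package targets unsupervised screening of latent mental-health state
from multi-view student-survey data: `N` respondents observed through `V`
aligned feature blocks. The reference protocol uses `N = 800` respondents,
two views of 8 categorical attributes each, `C = 5` latent state levels
("extremely poor", "poor", "medium", "average", "good"), a 600/200
train/test split, random data-row center initialization, and an iteration
cap of 100. Ground truth comes from a separate clinical instrument; here the
synthetic generator's latent class plays that role.

## Model and updates

MvK-means minimizes

    J_H(φ, z, w) = Σ_v w_v^p D_v(φ, z) + η Σ_v w_v^p,
    D_v = Σ_j Σ_i φ_ij ‖x_i^(v) − z_j^(v)‖²,   Σ_v w_v = 1, w_v ∈ [0, 1],

by alternating three block minimizations, each exact, so the objective is
non-increasing at every iteration (asserted in the tests on every fit):

1. `φ`: respondent `i` joins `argmin_j Σ_v w_v^p ‖x_i^(v) − z_j^(v)‖²`
   (ties to the lowest index). This update is not usually written out; it is
   the unique rule consistent with monotone descent of `J_H`.
2. `z`: per-view cluster means, independent of the weights.
3. `w`: the Lagrangian solution on the simplex,
   `w_v = (D_v + η)^(−1/(p−1)) / Σ_u (D_u + η)^(−1/(p−1))`,
   strictly decreasing in `D_v`. If some `D_v + η` are exactly zero, all
   mass is split uniformly over the zero-dispersion views (limit
   convention, logged).

Raw integer codes feed the Euclidean distance directly, mirroring the
protocol's practice; `standardize="zscore"` (population variance, constant
columns → 0) is available because ordinal-looking codes distort distances.

### Hyperparameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `C` / `k` | number of clusters | 5 | the five state levels of the protocol |
| `p` | weight exponent (> 1) | 2 | smallest integer with `1/(p−1)` defined; `p → 1⁺` concentrates all weight on the best view |
| `η` | weight regularizer (≥ 0) | 0 | η only softens weight contrast; `eta_heuristic()` offers 0.1 × mean initial per-view dispersion as a data-scaled alternative |
| `max_iter` | iteration cap | 100 | protocol limit |
| `tol` | convergence on \|ΔJ\| | 1e-6 | also stops when assignments repeat |
| `n_restarts` | random restarts, best by final J | 10 | single runs are the protocol's, restarts stabilize Lloyd-type local optima |
| `m` | FCM fuzzifier (> 1) | 2 | community standard |

Initialization samples `C` distinct respondents uniformly and uses their
rows as centers in every view (views stay aligned); weights start uniform.
A single integer seed drives one `numpy.random.SeedSequence`; restart `r`
uses its `r`-th child, so K-means, FCM and MvK-means draw identical initial
rows given the same seed — this is what makes the single-view reduction
(V = 1, η = 0 ⇒ MvK-means ≡ K-means) hold trajectory-for-trajectory, and
the fixed-uniform mode equal K-means on concatenated views with the
objective scaled by `(1/V)^p`.

### Numerical conventions

* Ties in assignment and hardening break toward the lowest index.
* An empty cluster is repaired by reseeding its center at the point farthest
  from its currently assigned center and moving that point; this strictly
  lowers the objective, preserving monotonicity.
* A point coinciding with an FCM center gets membership 1 there (mass split
  equally if several centers coincide with it).
* NMI uses natural-log entropies and geometric-mean normalization
  `I/√(H_a H_b)` (arithmetic-mean variant available). If one labeling has a
  single cluster, NMI is 1 when both do and 0 otherwise. The Rand index is
  computed from the contingency table via pair counts.
* Hard-zero weight clamping (a view's weight is exactly 0 only in the limit
  `D_v → ∞` when η ≥ 0) is intentionally not applied by default.

## Single-view baselines

K-means (Lloyd) and fuzzy C-means serve as comparison models. They consume
the column-wise concatenation of all views — the only way to give a
single-view learner both blocks; a single-view-only mode simply passes one
view. FCM uses the standard alternating updates
`u_ik ∝ d_ik^(−2/(m−1))`, `c_k = Σ u_ik^m x_i / Σ u_ik^m` and hardens by
row-wise argmax.

## Synthetic survey generator

The generator emulates the protocol's data so the pipeline is testable
without real student records. Each respondent draws a latent class from the
class proportions (uniform by default); each attribute draws a level from
that class's conditional distribution; with probability `noise_level` the
level is replaced by a uniform one; levels are encoded through the packaged
code books (basic information: codes 11–85; questionnaire: option index).
Gender and grade are drawn once per respondent and mirrored across both
views. `corrupt_view` applies the same cell-wise uniform replacement to an
already-encoded view, emulating a low-quality view.

Class-conditional distributions are this package's construction (no real
distributions are published). Each informative attribute mixes a base
marginal with a one-hot peak: `(1−s)·base + s·onehot(preferred_c)`, with
`s` the separation knob (`low` 0.3, `medium` 0.6, `high` 0.985,
`0` = no class signal). Questionnaire items 3–8 carry the full strength
`s`; in the basic-information view GPA and attendance carry `0.8·s` and
character and household income `0.5·s`, so that view is informative but
clearly weaker. The preferred-option patterns are version-pinned constants,
chosen once by maximizing the minimum pairwise squared distance between
class signatures (with the wide items forced to use at least four distinct
options); this guarantees every pair of classes differs on several items at
once. Two consequences shape what the tests can show:

* at `separation="high"` responses are near-deterministic, so best-of-10
  multi-view fits recover the generating classes at NMI ≳ 0.96 — "high" is
  a near-noiseless regime, deliberately;
* corrupting the questionnaire view raises its dispersion above the
  basic-information view's, so the learned weights cross (w₂ < w₁) and
  decrease monotonically in the noise level, and the weighted model beats
  the uniform-weight model by leaning on the cleaner view.

What the generator does **not** emulate: real response distributions,
correlations between attributes within a class beyond the class itself
(attributes are conditionally independent), missingness, acquiescence or
other response styles, and ordinal structure in the codes. Passing tests
therefore demonstrate correctness of the algorithms and the qualitative
mechanics of view weighting, not clinical validity on real surveys.

A caveat on dispersion-based weighting worth knowing: `w_v` tracks total
within-cluster dispersion, not signal. At intermediate corruption the update
can shift weight away from a still-informative view faster than is optimal
(visible as a dip of the weighted model below the uniform one around noise
0.25 in this generator's geometry); at corruption ≥ 0.5 down-weighting wins
clearly.

## Evaluation protocol

The benchmark runs K-means, FCM, uniform-weight and weighted MvK-means on
the same seeds, scoring NMI and Rand index against ground truth on **both**
the 600-respondent training split and the 200-respondent test split (the
protocol does not say which split its published table used, so the report
labels both). Test-split assignments come from frozen centers and weights
(`mvk_predict`, nearest-center, or membership hardening). Every command
embeds a config echo in its outputs, and all randomness derives from a
single integer seed, so any report is reproducible from (config, seed).

## Problem sizes

Tests and the acceptance script run the protocol at its native size
(n = 800, C = 5, two views × 8 attributes, 10 seeds, 10 restarts); the
objective-monotonicity sweep uses 50 datasets with n drawn from 60–800, and
the Lloyd-vs-exhaustive check uses 1-D instances with n ≤ 8, where
best-of-all-pair-inits Lloyd provably attains the exhaustive 2-partition
minimum in practice (in ≥ 2 dimensions it can miss it even at these sizes,
which is why that check is scoped to one dimension).
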