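# Methods

## The clustering model

The segmenter treats a grayscale image as `m = H·W` one-dimensional
feature points (pixel intensities, row-major) and fits `x` cluster
centers `v_i` with a fuzzy membership matrix `U` (`x × m`, columns
summing to 1), minimizing the penalized objective

```
A(U, V) = Σ_i Σ_k u_ik^w d_ik²  +  σ Σ_i Σ_k u_ik^w (1 − P_ik)^w
```

`d_ik²` is the squared Euclidean distance from point `k` to center
`v_i`; `w > 1` is the fuzzifier; `P_ik` averages the memberships of
class `i` over pixel `k`'s spatial neighbors (8-connected by default,
truncated at image borders, so `P` inherits column-stochasticity from
`U`). The penalty makes a membership that contradicts its neighborhood
cost extra, which is what suppresses isolated noise pixels. With
`σ = 0` both the objective and all updates reduce bit-for-bit to plain
fuzzy C-means.

The alternating updates are the stationarity conditions of `A` under
the column-sum constraint: with `g_ik = d_ik² + σ(1 − P_ik)^w`,

```
u_ik = g_ik^(−1/(w−1)) / Σ_j g_jk^(−1/(w−1)),
v_i  = Σ_k u_ik^w a_k / Σ_k u_ik^w .
```

A point with `g_ik = 0` for one or more classes splits its unit mass
equally among those classes (the limit of the update; deterministic).
Hard labels are the per-pixel argmax of membership, ties to the lowest
class index. The penalty exponent on `(1 − P)` defaults to `w`; an
exponent-1 variant is available as an option since both forms appear in
the spatially regularized FCM literature.

## Prior refresh and the monotone trace

`P` is lagged: each iteration rebuilds it from the previous
memberships, which keeps the U-update closed-form. Naive lagging,
however, does not give a monotone objective — early in a run the prior
swap can raise the penalty term faster than the U-update lowers it (we
observed increases up to ~0.3 on objectives of order 100 in roughly
half of randomly initialized runs). The implementation therefore moves
the prior toward its refreshed value by the largest dyadic step
`λ ∈ {1, 1/2, 1/4, …}` that does not increase the penalty at the
current memberships; since `(1 − P)^w` is convex in `P` and `λ = 0` is
always admissible, a valid step always exists. With this line search
the recorded trace is provably non-increasing: the U-update is optimal
for the prior it sees, the center update only shrinks the distance
term, and the prior step never raises the penalty. In practice the full
refresh (`λ = 1`) is accepted at almost every iteration and the final
prior agrees with the neighborhood average of the final memberships.

Convergence is judged jointly: the run stops when both the maximum
center shift and the maximum membership change fall below `tol`.
A centers-only rule is not enough — with a well-initialized start
(e.g. from the GA) the centers are stationary almost immediately while
the prior and memberships are still equilibrating, and stopping there
leaves a visibly unconverged partition.

## Initialization

Random initialization draws `x` distinct points *in feature space*
(distinct unique intensity values when enough exist, otherwise distinct
pixels): coincident centers produce identical membership rows and can
never separate.

The genetic algorithm searches over candidate center sets (`x × b`
float genomes). Population seeding follows the 3-sample rule: each
center of each individual is the mean of 3 data points drawn without
replacement, so genomes start inside the data hull. Fitness is the
reciprocal `1/A` of the penalized objective evaluated with a single
membership pass from the genome (plain-FCM memberships supply the
prior), capped at 1e12 when `A < 1e−12`; a single pass keeps a
generation at `O(n·x·m)`. Note the cap is reachable only when the
spatial term is off — any image with a class boundary pays a strictly
positive neighborhood penalty even at the exact generating centers.
Operators are tournament-2 selection, arithmetic blend crossover
(`λ ~ U(0,1)` per pair, probability 0.8), per-gene Gaussian mutation
(probability 0.1, scale 0.1 × data range, clipped to the range), and
elitism of one, which makes best fitness non-decreasing. Defaults:
population 20, 50 generations, early stop after 10 stagnant
generations. All randomness flows from one injected generator, so runs
are fully reproducible under a seed. For non-image data the spatial
term has no meaning and fitness falls back to the plain FCM objective.

Where initialization matters: on images whose classes are all large,
random starts and GA starts converge to the same optimum and differ
only at the level of convergence residue. The GA earns its cost when a
class is rare — on three-class lesion phantoms (a ~5 %-of-pixels bright
disk), random pixel-value starts regularly merge the lesion into a
neighboring class while the GA start finds it, improving the final
objective by two to three orders of magnitude more than the
run-to-run noise.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `w` (fuzzifier) | 2.0 | membership softness; > 1 strictly |
| `σ` | 1.0 | spatial penalty weight, balanced for intensities in [0, 1] |
| connectivity | 8 | neighborhood of the prior (4 selectable) |
| `tol` | 1e−5 | joint stop: max center shift and membership change |
| `max_iter` | 300 | iteration cap |
| GA | 20 × 50 | population × generations; p_c 0.8, p_m 0.1, elitism 1 |

Intensities are arbitrary units kept as floats; the CLI normalizes to
[0, 1] before clustering (constant images map to zero) so the default
`σ` is meaningful. Degenerate empty classes are re-seeded at the
worst-covered point with a warning (never observed in the test
conditions).

## Validity indices and diagnostic arithmetic

Partition coefficient `F ∈ [1/k, 1]` and partition entropy
`H ∈ [0, log k]` (natural log, `0·log 0 = 0`) measure partition
crispness. The compactness/separation index divides the mean fuzzy
scatter `(1/n) Σ u² d²` by the minimum squared point-to-center
distance; that denominator is zero whenever a point sits on a center,
so it is floored at 1e−12 with a warning, and a center-pair
(Xie–Beni-style) denominator is available as a non-default mode.

Diagnostic metrics are computed as exact rationals and rounded half-up
to two decimals only for display. The marginal solver enumerates every
feasible TP count given the four marginals, derives the other three
cells, and keeps tables whose five metrics round to the published
values; it demands a unique survivor and otherwise raises with the full
candidate list. For the study marginals (121/38 vs 128/31) the unique
survivor is TP=117, FP=4, FN=11, TN=27.

## Phantoms: what they emulate and what they do not

Phantoms paint piecewise-constant regions (full frame, half-plane,
disk, annulus, lobulated blob — a disk with random boundary bumps,
echoing lobulated lesions) at distinct mean intensities, then add
Gaussian noise, replace a chosen fraction of pixels with uniform
outliers, and optionally multiply a smooth radial-quadratic bias field.
Segmentation quality is the misclassification rate under the best
label permutation (Hungarian assignment on the confusion matrix).

These phantoms capture the piecewise-constant-plus-noise structure the
clustering model assumes; they do not simulate contrast-agent kinetics,
partial-volume edges, anatomical texture, or correlated acquisition
noise. Passing the phantom suite therefore demonstrates correctness of
the optimization and its noise robustness in the model's own regime,
not clinical-grade performance on real DCE-MRI.

## Problem sizes used in the standard runs

The validation runs use 64×64 phantoms (4096 pixels), 10 seeds for
aggregate statements, and the GA defaults above; a full
comparison (GA + penalized FCM + plain FCM, 10 seeds) completes in
tens of seconds. On noiseless two-region phantoms the recovered centers
sit within `0.2 × (boundary fraction)` of the generating means — the
boundary pixels' penalty pulls them inward slightly — which is below
1e−3 for widths ≥ 32.

## Known limitations

- The penalized objective is non-convex; all guarantees are descent
  and determinism, not global optimality.
- The prior line search is a safeguard: its guarantee is monotonicity,
  and the scheme remains a heuristic for the self-consistent
  minimum of `A` with `P = prior(U)`.
- 2-D single-channel only; no 3-D neighborhoods, DICOM, registration,
  or bias-field correction.
- The compactness/separation index in its default (literal) form is
  dominated by the epsilon floor whenever any point coincides with a
  center; use the center-pair mode for a scale-meaningful value.
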