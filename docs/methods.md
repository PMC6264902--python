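# Methods

## Model

The retina is an *n* × *m* binary lattice *a<sub>ij</sub>* ∈ {0 (red/pale),
1 (green/yellow)}, generated column by column in the order the
morphogenetic furrow sweeps the eye (column 0 posterior-most). The model
composes three pieces.

**Column defaults.** The structured component assigns each column a default
green probability *s<sub>j</sub>*. Under the mechanistic parameterisation a
furrow-borne factor X gates a threshold switch,

    s_j = P0        if X_j <= X0        (boundary on the lower branch)
    s_j = 1 - P0    if X_j >  X0
    X_{j+1} = gamma - beta * s_j,

with gamma > 0. Two candidate fixed levels exist, X_A = gamma −
beta(1−P0) (reached after a green-default column) and X_B = gamma −
beta·P0 (after a red one). A level is self-consistent when it reproduces
the default that generated it (X_A above threshold, X_B at or below).
`classify_regime` reports:

- *alternating* — neither self-consistent: X hops between the levels,
  giving period-2 stripes (e.g. beta=8, gamma=10, X0=5, small P0);
- *fixed_high* / *fixed_low* — exactly one self-consistent;
- both self-consistent — *bistable* when P0 > 0.5 (the overlap region of
  the phase diagram, where the outcome depends on the initial X); for
  P0 ≤ 0.5 (the beta < 0 uniform-fly case) the conventional
  above-threshold initial condition selects the green branch and the label
  is *fixed_high*;
- *invalid* — X0 < 0, which is physically inadmissible (X is a biological
  factor). `ModelParams` accepts such values so the classifier can label
  them; simulation rejects them.

The simulator starts the X relay just above threshold (first column
defaults green) unless `x_init` is given. On the beta < 0 branch the
structured component is the constant uniform-fly probability
`P_ordered` = 0.99 rather than the X relay, matching how that branch of
the mixture is defined. For inference, (beta, gamma) are replaced by the
four-valued mode m ∈ {fr, fg, ar, ag}: fixed point vs alternation ×
low(red)/high(green) start, with s_j given in closed form (ag: 1−P0 on
even columns; ar the complementary phase; fg/fr constant). The closed
forms are tested against iterating the threshold switch directly.

**Mistake propagation.** Each column has a *type* (G or R). For the
correction machinery the type comes from the column's structured default
(type G iff s ≥ 0.5); when no default is available the realized majority
is used, ties going to G. Mistakes are cells disagreeing with the type.
They perturb the next column through

    l_ij = epsilon * sum_{i' in mistakes} exp(-(i - i')^2 / k) * (T - s_j),

where T is the previous column's type value (equivalently 1 − a for each
mistake, since all mistakes share one colour) and s_j the current column's
uncorrected structured default. The corrected structured component is
clip(s_j + l_ij, 0, 1); clipping is needed because overlapping kernels of
clustered mistakes can push the sum outside [0, 1]. The kernel is Gaussian
in row distance with squared-distance scale k, one reading of
"correlations decrease exponentially with distance"; the alternative —
k as the scale rather than its square — would make the canonical k-grid of
perfect squares (1, 4, 9, …, 625) a grid of plain distances 1…25. We adopt
the squared-distance reading and keep k = 1 (nearest-neighbour range) as
the default and throughout the recovery study.

Anchoring the type on the default rather than the realized majority
matters for perturbations: a normally-green column drawn at P_per = 0.5
keeps type G, so its red draws are the mistakes whatever way the majority
tips. With majority-anchored types, half of all perturbed realizations
flip majority and the correction then *reinforces* the next default,
erasing the perturbation (measured mean profile 12.6 → 7.0 → 1.7 → 0.25
mistakes/column); default-anchored types give sustained propagation
(12.6 → 10.0 → 7.1 → 4.9 → … → 0.3 at column 20), the published domain
behaviour. For measurement (`pattern_stats`) mistakes remain defined
observationally, against the realized column majority, with 50/50 ties
labelled by the alternation phase of the nearest untied column and
flagged.

**Mixture.** The site probability is

    P_ij = alpha * clip(s_j + l_ij) + (1 - alpha) * (1 - P0_droso).

The correction lives inside the structured component: at alpha = 0 the
model is an exact iid Bernoulli mosaic (no correction term, "total absence
of correlations"), and the influence of epsilon, P0 and the mode shrinks
with alpha. Adding l after mixing would instead correlate even the
alpha = 0 limit and contradict the stochastic-eye phenomenology. The
stochastic component's green probability is 1 − P0_droso, so
P0_droso = 0.35 reproduces the 35:65 pale:yellow ratio.

**Perturbation.** `Perturbation(t, P_per)` draws every cell of column t
iid at exactly P_per — the insult replaces that column's decision
probability wholesale, so corrections into it are suppressed — while
corrections out of it proceed normally with its unperturbed type.

## Simulation conventions

Draws are Bernoulli per site in fixed column-major, top-to-bottom order
from one `numpy` Generator, so a seed fixes the pattern bit-for-bit. The
lattice is stored rectangularly; hexagonal packing is a rendering concern
only (alternate columns offset half a row), and rendering flips the x-axis
so anterior appears left. The study size is 30 rows × 50 columns.

## Statistics

⟨R^h⟩ is the Pearson correlation over all pooled horizontally adjacent
site pairs (a_ij, a_{i,j+1}); pooled pairs and row-averaged variants agree
on the anchors (−1 stripes, 0 random), pooled adopted. A constant input
returns NaN rather than 0 so the uniform fly stays distinguishable from
the random fly. ⟨R^v⟩ averages within-column lag-1 correlations over the
columns where they are defined: a striped retina with internally uniform
columns reports NaN (no within-column structure) instead of the pooled
artifact +1. The phase diagram scans mean ⟨R^h⟩ over (branch, alpha,
P0_droso) with the beta > 0 branch using the alternating component and the
beta < 0 branch the uniform fly.

## Likelihood and inference

Every P_ij depends only on parameters and the realized previous column, so

    log L = sum_ij [ a_ij log P_ij + (1 - a_ij) log(1 - P_ij) ]

is the exact pattern probability — no latent marginalisation, X being a
deterministic function of the defaults. This is verified by brute force:
on small lattices the probabilities of all 2^(nm) patterns sum to 1 to
1e−12, including with epsilon > 0, and the per-site probabilities the
likelihood reconstructs equal the simulator's own draw trace. Cells with
probability 0 under a deterministic grid point yield −inf; an optional
probability floor (off by default) lets such grid points score imperfect
data.

Grid-search ML evaluates every eligible combination of (m, alpha, epsilon,
P0, k). Two presets mirror the canonical discretisations: *simulated*
(alpha step 0.01 over [0, 1]; epsilon ∈ {0, …, 0.5} step 0.1; P0 ∈ {0,
0.1}; k = 1) and *real-data* (alpha ∈ {0.01, …, 0.99}; P0 ∈ {0.01, 0.02,
0.04, 0.08, 0.16}; epsilon ∈ {0, …, 0.010} step 0.001; k over perfect
squares to 625 — the published "32" entry breaks the square sequence and
is treated as a typo for 25). Fixed-point modes pin P0 = 0 because alpha
and P0 are fully interdependent there. The stochastic component's constant
is not searched; it is fixed at P0_droso = 0.5, which keeps the family
identifiable and spans red-biased (fr: P = (1−alpha)/2) through
green-biased (fg: P = (1+alpha)/2) iid mosaics. Ties are broken
deterministically in favour of the lexicographically first grid point
(mode order fr, fg, ar, ag, then ascending alpha, epsilon, P0, k) and all
co-maximal points are reported — e.g. epsilon is unidentifiable on a
mistake-free pattern and ties across its whole grid. The batched evaluator
exploits that the corrected structured component is alpha-independent; it
is cross-checked grid-point-by-grid-point against the reference
single-parameter likelihood in the tests.

The recovery study draws true parameters uniformly from the eligible grid
combinations, simulates one 30 × 50 pattern each, re-infers, and
aggregates by true alpha in 0.1-wide bins (mean inferred alpha, mean
absolute errors, mode misidentification rate) and by true epsilon. The
shipped study uses 200 realizations, enough to resolve the identity-curve
tracking and the error-vs-alpha trend while keeping the default test run
fast. Spearman rank correlations carry two-sided permutation p-values
(identity permutation counted, so p > 0; exact enumeration below n = 9,
random permutations otherwise).

## What the synthetic data does and does not show

The simulator doubles as the data generator for all tests: ordered
(alternating-column), random (iid Bernoulli) and intermediate mosaics,
with optional perturbed columns. It emulates the lattice-level statistics
of real retinas — stripe order, mosaic randomness, mistake propagation —
but not their geometry (eye curvature, the ~25 × 30 ommatidial counts,
the dorsal rim area) nor any molecular detail (the identity of X, R7/R8
coupling). Passing tests therefore demonstrate internal consistency of
simulation, statistics and inference, and recoverability of parameters
from model-generated data; they cannot validate the model against
photographs of real eyes, which are outside this package's scope.

## Known limitations

- The exact functional form of the correction term in the original
  formulation is not published; the Gaussian kernel here is one compliant
  choice, and quantities that depend on its tails (e.g. propagation decay
  lengths) are form-dependent.
- With epsilon near 1 and k ≥ 1 single mistakes themselves propagate with
  high probability; the regime where isolated mistakes are "immediately
  corrected" is the epsilon → 0 limit.
- Grid-search ML scales linearly with the grid; the real-data preset
  (~327k points) takes seconds per 30 × 50 pattern rather than the ~0.1 s
  of the simulated preset.
- Inference assumes the furrow direction and row registration of the input
  pattern are known.
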