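# Methods

This note records the models implemented in `uniexact`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Statistic

The functional chi-squared statistic is computed in the algebraically
expanded form

χ²_f = s · [ Σᵢ (Σⱼ n²ᵢⱼ)/nᵢ· − (Σⱼ n²·ⱼ)/N ],

which is exact in rational arithmetic (`fractions.Fraction`) and makes the
zero-row convention automatic: a row with nᵢ· = 0 has every cell zero and
simply drops out of the sum, the 0/0 limit of the per-row chi-square.  The
public API returns floats; all enumeration internals keep the rational
values so that equality of statistic values is decided exactly, not by
rounding.  Float inputs to p-value lookups (e.g. a statistic provided by a
caller) are compared with a shared relative tolerance of 1e-9.

The statistic is ≥ 0 for every table (checked exhaustively for small
shapes in the test suite); a negative value would signal a bug, and the
`TestResult` constructor rejects it rather than clamping.

## Null populations and exact arithmetic

Both null populations concentrate on the embedded k×k uniform square,
k = min(r, s).  Every table probability used in the tests reduces to an
integer weight — the multinomial coefficient N!/Π nᵢⱼ! — divided by a
population total:

- fixed-total (UMFT): Pr(A) = w(A)/k^(2N), since every square cell has
  probability 1/k²;
- fixed-margins (UEFT): Pr(B) = w(B)/Σ_B w(B), since the hypergeometric
  prefactor (Π Rᵢ!)(Π Cⱼ!)/N! is constant over the population.

Enumeration therefore sums integers and normalizes once, so exhaustive
probability sums are exactly 1 and the brute-force and fast engines agree
bit-for-bit.  The standalone `multinomial_prob` / `hypergeometric_prob`
functions, which must handle single tables in isolation, use cached
log-gamma arithmetic instead.  The printed form of the fixed-margins law
found in some descriptions omits a factorial on the row sums; the
implementation uses the standard (Π Rᵢ!)(Π Cⱼ!)/(N! Π nᵢⱼ!) form, whose
normalization to 1 is verified by enumeration in the tests.

Near-uniform margins place the ⌈N/k⌉ counts on the lowest-indexed levels.
The choice is canonical: permuting which levels receive the remainder
leaves the null distribution unchanged (tested).

## Continuity correction

UEFT p-values form a step function of the observed statistic.  UEFTC
locates the lower neighbor (largest achievable null statistic ≤ observed;
defined as 0 with tail 1 when the observed value is below the null
minimum), the upper neighbor (smallest achievable ≥ observed; always
exists because both populations share the same maximum statistic), and the
super neighbor (smallest strictly above the upper; its tail is defined as
0 when the upper neighbor is the null maximum).  Averaged boundary values
Pl = (P(Bl)+P(Bv))/2 and Pv = (P(Bv)+P(Bw))/2 anchor a linear
interpolation at the observed statistic; an observed statistic equal to an
achievable value receives Pv directly, and statistic 0 receives p-value 1.
When the null has a single distinct value (degenerate tiny populations)
the super neighbor is undefined and the at-maximum convention applies, so
the correction interpolates toward P(Bv)/2; this sub-case, and the
sub-case where an observed value below the null minimum still uses
P(O) = P(Bv) = 1, are conventions of this implementation for situations
the correction's defining cases leave open.

The corrected value always lies within the smoothing band
[P(Bw), P(O) + (P(Bl) − P(Bw))/2], is in [0, 1], and is non-increasing in
the observed statistic (tested exhaustively on small shapes).

## Fast engine

Rows are filled in deterministic lexicographic order.  Because row sums
are fixed at R₀, each row contributes (Σⱼ n²ᵢⱼ)/Rᵢ additively to a
running total Q, and the column-adjustment term is a constant over the
fixed-margins population — so the engine memoizes the distribution of the
remaining rows' Q-contribution keyed by (rows remaining, *sorted* residual
column capacities).  Columns with equal residual capacity are
interchangeable, which collapses the state space drastically under
near-uniform margins: the full exact null distribution for a 3×3 table
with N = 40 takes ~20 ms, versus an infeasible direct enumeration.
Weights are integers and values rationals, so "fast = brute force" is an
exact identity, asserted per observed table in the tests.

A classical pruned traversal (`tail_weight_pruned`) with certified
per-state bounds — each unfilled row of sum R contributes at least R/m
(even spread over the m positive columns) and at most min(R, max residual
capacity) — demonstrates the branch-and-bound formulation: subtrees
entirely above the threshold contribute their conditional mass without
expansion, subtrees entirely below are discarded, and pruning provably
never changes the tail.  The distribution-building DP is the default
engine because UEFTC needs the neighbor statistics anyway.

## Synthetic data generator

`simulate` produces the two table classes used throughout validation:

- **independent**: N iid draws from the product of configurable row and
  column marginals — `uniform`, or `power8` with Pr(i) = i⁸/Σₘ m⁸, a
  sharply skewed law that concentrates mass on the last levels and is the
  stress case for margin-sensitive methods;
- **functional**: a map f drawn uniformly among non-constant maps
  [1..r] → [1..s] (constant functions carry no directional signal and are
  excluded), X drawn from its marginal, Y = f(X) passed through a noise
  channel.  Y's marginal is never configured directly — it is determined
  by X's marginal and f.

The noise channel is a geometric distance-decaying kernel,
Pr(j | y) ∝ ν^{|j−y|} with noise level ν ∈ [0, 1]: the identity at ν = 0,
uniform over all levels (hence independence of X) at ν = 1, with
displacement probability decaying with level distance in between and the
median statistic of functional tables decreasing monotonically in ν
(tested on the grid 0.01–0.9).  For s = 2 the flip probability is
ν/(1+ν).  This kernel is this package's stand-in for level-displacement
noise on an ordered discrete scale; it is isolated behind the
`noise_channel` interface so an alternative kernel can be swapped without
touching any test.  Consequences for interpreting results: passing
behavioral tests show the tests' operating characteristics under *this*
noise law and *these* marginals — they do not certify behavior under
other noise processes, under noise acting on X, or on real data, and
figure-level comparisons published for other simulators' noise models are
not expected to reproduce numerically.

Default grids mirror the validation conditions at reduced scale: noise
∈ {0.01, 0.15, 0.3, 0.45, 0.6, 0.75, 0.9}, N ∈ {8, 12, ..., 44};
replicate counts are arguments, not constants.

### Direction-identifiable patterns

A non-constant map from a 2-level X is necessarily injective, making the
table a bijection on its support: X and Y determine each other, neither
direction is "truer", and output-side noise actually makes the reverse
direction look cleaner.  Direction-recovery claims therefore only make
sense for **many-to-one** patterns, and the generator's
`function_kind="many_to_one"` mode (requires r ≥ 3) rejects injective
maps.  The direction-recovery checks in the test suite use square 4×4,
landscape 4×7 and portrait 7×2 shapes — each of which can host a
many-to-one non-constant function — at noise 0.1 and N = 30.

## Evaluation harness

`run_benchmark` computes power and type-I error at a declared α
(p-value methods only; the reference statistics CE/FOI/GKT have no
p-values and are excluded from those metrics, available for ranking
metrics only) and AUROC/AUPR by ranking pooled functional and independent
tables per method via scikit-learn.  Entropy-based scores use base-2
logarithms; the base cancels in rankings.  Direction contrast applies the
transform −log(ratio + 0.01) + log(1.01) to the ratio of per-direction
scores, inverting the ratio for statistic-valued methods so a positive
contrast always means row → column; ties (|contrast| < 1e-12) are
reported as such rather than forced, and count against a method when the
truth is directed.  Fisher's exact test (2×2 only) and the G-test come
from scipy.

## Known limitations

- UMFT is exponential in N and guarded by a configurable enumeration cap
  (default 5×10⁶ tables); it is a gold standard, not a production path.
- The embedded-square null makes p-values comparable across tables, but
  observed tables whose shape is far from the square can reach the null's
  tail by chance: strongly portrait independent tables (e.g. 7×2 at
  N = 30) receive small p-values at a rate well above nominal.  Type-I
  calibration statements in this package are made for near-square shapes
  (tested at 3×3), and shape-bias comparisons against score-based methods
  depend on the noise model and are not asserted by the test suite.
- The fast engine's memoization assumes the fixed-margins (UEFT) null;
  UMFT gains no column-constant simplification and stays brute-force.
- Inputs must already be discrete; the package neither discretizes
  continuous data nor imputes missing observations.
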