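# Methods

This note documents the models and procedures implemented in
`bulksense`, the defaults they ship with, the numerical choices made
where the design was genuinely open, and the limits of what the
synthetic-data experiments can show.

## Problem and encoding

The sludge volumetric index SVI (cm³/g) measures the settleability of
activated sludge; exceeding a limit value SVI_lim (default 150 cm³/g)
defines *bulking*. The package works with the binary state throughout:
label 0 = bulking where SVI > SVI_lim strictly, label 1 otherwise (the
boundary value counts as non-bulking). Classification quality follows
the convention of the source domain: **SPEC** is the correct-
classification rate among bulking records and **SENS** among
non-bulking records. This is swapped relative to the usual clinical
vocabulary; the package keeps the domain convention consistently and
says so wherever the terms surface.

Predictors are taken one record before the response (lag 1 by default):
the sensor is predictive, driven by yesterday's influent and operating
state. Ratio features such as BOD/TN are element-wise quotients of the
lagged values; a zero denominator or missing value drops the row (no
imputation) with a warning that reports the count.

## Classifier bench

Five families are trained per candidate predictor set:

- **LR** — maximum-likelihood logistic regression, no penalty.
- **BT / RF** — gradient-boosted trees and random forests; the tree
  count is selected from a grid capped at 300 by internal validation.
- **MLP** — a single-hidden-layer perceptron explored over hidden sizes
  j…2j+1 (j = number of inputs) and five hidden activations: linear,
  exponential, logistic, sine, tanh. Because no mainstream library
  implements exponential or sine hidden units, the network is
  implemented in-package (logistic output, cross-entropy loss with a
  small L2 term, analytic backprop, L-BFGS). The exponential activation
  clips its argument to ±30 so eˣ cannot overflow; inputs are
  standardized internally.
- **SVM** — Gaussian-kernel support vector machine over a (C, γ) grid
  (defaults C ∈ {10, 100, 1000}, γ ∈ {0.1, 0.25, 0.5}).

Data are split 75/25 into learning and test partitions by a seeded
random split, stratified by class so both classes appear on both sides
when counts permit (a single-record class is forced into learning with
a warning; a chronological mode is available). Hyperparameter searches
are exhaustive seeded grids minimizing (1−SENS) + (1−SPEC) on a second
seeded 75/25 split *of the learning partition*; the test partition is
never consulted before final evaluation. Probabilistic families
classify at threshold 0.5 (configurable). Before model building, a
one-way F-test between the two label groups screens predictors;
those with p > 0.05 are flagged for omission.

Ranking uses max min(SENS, SPEC), ties broken by SENS+SPEC and then by
a fixed simplicity order LR > BT > RF > SVM > MLP (an analytical
equation beats a tree ensemble beats a kernel/network model at equal
fit). A Pareto front over (number of variables, fit) exposes the
cost–accuracy trade-off directly.

## Weight system

For a candidate set the quality side contributes the count fraction
δ = (#included quality indicators)/q and the cost fraction
f(δ) = ΣK(z_i)/ΣK_all with default q = 3 and K(TN)=3 > K(TP)=2 >
K(BOD)=1; the operational side contributes λ and f(λ) analogously with
g = 3 and K(MLSS)=3 > K(DO)=2 > K(T)=1. The duration penalty f(t) is 1
when any included quality indicator needs more than 24 h to determine
(default: only BOD) and is suppressed for indicators marked as
obtainable from a statistical surrogate. The controllability flag F(S)
is 0 when the set contains at least one operator-adjustable variable
(defaults MLSS, DO, T, m_PIX) — controllable sets are *rewarded*,
since only they can be used to steer SVI.

The cumulative weight sums the blocks:
W_tot = (δ + f(δ) + f(t)) + (λ + f(λ)) + F(S). The brace notation of
the source formulation is ambiguous between summing and minimizing
within a block; summing is the default because it makes the combined
boundary condition π₃ exactly π₁ + π₂ and turns the minimum-weight rule
into a plain argmin over candidate sets. A `min` aggregation variant
remains available behind `WeightConfig.aggregation`. Ties in the argmin
break by fewest variables, then lexicographic member order, so results
are reproducible regardless of input order. All fractions are exact
rationals (`fractions.Fraction`).

Ordinal cost weights are judgments, not measurements, so a Monte Carlo
mode redraws every K uniformly from {K−1, K, K+1} (values clipped below
at 1 — the boundary value is therefore twice as likely for K = 1),
recomputes the cost fractions with the redrawn denominators, and
summarizes W_tot by mean, SD and quantiles. The ±1 window is a default,
not a claim about elicitation error; it is overridable.

## Selection matrices

Combinations are binned by their exact cost coordinates
(f(δ), f(λ)) ∈ {0, 1/6, …, 1}². Cost levels, not counts, key the cells
because the cost fractions are what the worked examples index by;
counts stay available per cell as metadata. When several combinations
share a cell, the cell's method is the winner over the union of their
fit rows, with per-combination winners retained. The logit-preferred
mode replaces the winner with LR-EX where the logistic model attains
SENS and SPEC > 0.9 in some member combination, LR-VG above 0.8, and
falls back otherwise.

Feasibility masking is conservative: a cell becomes infeasible (X)
only when *every* member combination violates the active constraint
(duration f(t)=1, or controllability F(S)=1); the overall mask is the
product of the two components. With the default costs the quality
levels 1/6, 4/6 and 6/6 are reachable only through BOD, so the duration
constraint masks exactly those columns of the printed-layout grid —
the transposed writer reproduces that pattern with its f(t) header row
0 1 0 0 1 0 1.

## The shipped logistic sensor

The full-scale plant fit decomposes as X = τ + ω:

    τ = 28.24 − 0.68·T − 2.66·MLSS − 1.82·DO − 0.56·m_PIX
    ω = 0.0008·L_TN + 0.0009·L_TP + 0.0001·L_BOD

with p = eˣ/(1+eˣ) the probability of bulking. Loads are
L = Q[m³/d] · C[mg/l] / 1000, i.e. kg/d — the only conventional unit
for which the load terms are commensurate with the controlling terms
(ω ≈ 4 and τ ≈ 1 at seasonal mean conditions; raw g/d products would
give |X| ~ 10³). The published coefficient table is ambiguous about the
smallest load term (it can be read as a second L_TP term); the package
defaults to L_BOD, consistent with the decomposition's definition, and
preserves the literal reading behind `third_load="TP"`. The probability
is computed with a saturating sigmoid, so extreme X neither overflow
nor produce values outside [0, 1].

## Sensitivity analysis

The sensitivity coefficient is the probability ratio
S = p(x + Δx) / p₀(x) over a Cartesian grid of signed offsets for one
to three simultaneously perturbed inputs; offsets are relative
(default grid ±30% in 5% steps, the framing of sensor miscalibration)
or absolute. The grid always contains the zero-offset point, where
S = 1 identically. Because operating-parameter errors enter only
through τ, a τ-aggregate axis stands in for any (MLSS, DO, …) error
combination producing the same shift; the implementation verifies this
equivalence exactly. Only sign and monotonicity properties are asserted
in tests — the reference surfaces exist only as figures, so no numeric
surface is claimed.

## Synthetic data

Each variable is drawn from a season-specific truncated normal whose
(min, mean, max, SD) reproduce the published winter and spring–fall
summary statistics; the default season mix is 50/50. Marginals are
independent — no correlation structure is published — with an optional
Gaussian-copula hook for rank-correlated stress tests. The bulking
state of record t is Bernoulli(p) with p from the shipped sensor
evaluated on record t−1, then flipped with probability `label_noise`
(default 0.05, a small labelling-error rate); SVI is then drawn
uniformly within the season's observed band on the matching side of
the limit, so label and SVI are mutually consistent by construction.
The winter SVI band (154–291 cm³/g) lies entirely above the limit, so
non-bulking winter draws fall back to the pooled across-season band;
SVI magnitude carries no information beyond the binary state and is a
modelling convenience, not a claim about the plant.

Under these conditions about 92% of records bulk and the mean linear
predictor sits near 5.5 with SD ≈ 3.6. Two consequences matter for
interpreting the experiments:

- **Identifiability.** The L_TP, L_BOD and m_PIX terms contribute only
  ≈ 0.09, 0.45 and 0.15 SD to the linear predictor, and the three loads
  are collinear through Q. Their coefficients are therefore weakly
  identified at n = 5000: refits recover the strongly identified
  hardware-sensor coefficients (T, MLSS, DO, L_TN) reliably — signs
  correct in 20/20 seeded replicates — but not the small load terms.
- **Noise attenuation.** Label-flip noise bounds the observed class
  probabilities away from 0 and 1, which biases plain logistic
  maximum likelihood toward zero; at |X| ≈ 5 a 5% flip rate attenuates
  coefficients by roughly 60–80%. Full-vector coefficient recovery to
  15% at these settings is therefore not achievable by an unbiased-link
  refit, and the acceptance experiment reports the measured recovery
  rate rather than asserting success.

Passing tests on this generator show that the pipeline is internally
consistent (labels ↔ SVI ↔ sensor, seeded determinism, screening and
split behaviour); they do not show that any classifier family would
reach the plant campaign's SENS/SPEC values on real records, which are
not deposited. The packaged fit table ships verbatim for exercising the
ranking and matrix machinery, not for re-derivation.

## Problem sizes and numerical defaults

The test suite and the acceptance script run everything at deliberately
modest sizes — records of 300–5000 rows, 20-replicate recovery
experiments, tree grids of 2–5 points — chosen as the smallest sizes at
which the checked properties are stable across seeds. Degenerate inputs
are handled explicitly: single-class partitions raise, constant
predictors screen out with p = 1, empty candidate lists raise, p₀ = 0
makes the sensitivity ratio undefined and raises, and non-convergent
fits are flagged on the returned model rather than silently accepted.
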