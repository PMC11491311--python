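# Methods

## The model

`symptomnet` estimates an **Ising model**: an undirected graphical model over
binary symptom indicators x ∈ {0,1}^p with joint distribution

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} β_ij x_i x_j ).

τ_i is a node's threshold (its log-odds of being present when no neighbour
is active) and β_ij the pairwise coupling; β_ij ≠ 0 means nodes i and j are
conditionally dependent given all other nodes.  The conditional of one node
given the rest is logistic,

    P(x_i = 1 | x_−i) = logistic( τ_i + Σ_{j≠i} β_ij x_j ),

which licenses estimation by nodewise logistic regression.  We use {0,1}
coding throughout because it matches this logistic parameterization; the
{−1,+1} spin coding used in physics is the affine map s = 2x − 1, under
which τ' = τ/2 + Σ_j β_ij/4 and β' = β/4.

## Estimation: eLASSO

For each node i, an L1-penalized logistic regression of x_i on all other
nodes is solved along a decreasing grid of penalties λ.  Per λ the fitted
model is scored with the extended Bayesian information criterion

    EBIC(λ) = −2ℓ + k log n + 2 γ k log(p−1),

where ℓ is the (penalized-fit) log-likelihood, k the number of nonzero
slopes, and γ the extra sparsity weight; γ = 0.25 by default, the setting
that trades some false-positive control for fewer missed edges.  The
EBIC-minimizing model is selected per node; equal-EBIC ties resolve to the
larger λ (sparser model), matching EBIC's preference for fewer neighbours.
An undirected edge is kept under the **AND rule** (default) only when both
directed slopes b_ij and b_ji are nonzero; its weight is their arithmetic
mean.  The OR rule (either nonzero) is available.  Thresholds τ̂_i are the
selected intercepts.

Numerical choices:

- **λ grid**: 100 log-spaced values from the analytic per-node
  λ_max = max_j |X_jᵀ(y − ȳ)|/n down to 0.01·λ_max.  The floor guards the
  divergence of the unpenalized MLE on separable data.
- **No predictor standardization**: binary 0/1 columns enter raw so
  coefficients stay on the log-odds scale the Ising parameterization needs.
  (Standardizing, as glmnet does by default, re-weights the penalty by each
  column's standard deviation; on these data the two variants give closely
  similar networks.)
- **Solver**: cyclic coordinate descent on the iteratively-reweighted
  least-squares quadratic surrogate (proximal Newton), specialized to
  binary predictors stored column-sparse, warm-started along the grid;
  convergence at max parameter change < 1e-7, at most 1e4 sweeps per λ.
  Coefficients with |b| ≤ 1e-10 are snapped to exact zero so support
  counts are meaningful.  The intercept is unpenalized.
- **Separation guard**: coefficient magnitudes are capped at 15 (odds
  ratios beyond e^15 are not distinguishable from infinity at these n);
  a warning reports capped updates.
- **Degenerate inputs**: a constant column is an error at `fit_ising`
  (the caller must drop or regenerate); the pipeline drops such nodes
  before fitting and records them, with reasons, in the run report.  A
  constant *predictor* column in a single nodewise regression is forced to
  zero with a warning; a single-class response is an error naming the node.

Tests verify the solver against an independent convex optimizer (L-BFGS-B
on the smooth bound-constrained split b = b⁺ − b⁻) to 1e-6 in objective
value, and EBIC selection against a brute-force scan of the grid.

## Dichotomization

Ordinal items are mapped to present/absent per instrument: HADS (0–3)
1-or-above → present; BIS-11 (1–4) 3-or-above → present; EQ-5D-5L
dimensions (1–5) any problem level → present; the Likert adherence item T8
(0–4) 1-or-above → present; the yes/no adherence items pass through.
MATE-Q substance frequencies count as present at any past-month use, except
heavy drinking, which uses the sex-specific weekly-units cut-off
(>21 men, >14 women, strict).  Reverse-keyed items (flagged in the
instrument tables) are reflected (scale_min + scale_max − x) **before**
thresholding so that 1 uniformly means "problem present"; for these
instruments the source tables flag the items but not the mechanism, and
reflection-first is the choice that preserves symptom-presence semantics.
Two nodes have no published rule and use documented stand-ins: multiple
partners = ≥2 in the past year; the VAS node QV = 1 below the within-sample
median (the least parametric split for the only continuous node; both are
configurable).  Missing ordinal responses are median-imputed per item;
an even-count median falling between two codes rounds down (conservative
toward "symptom absent").  Prevalence percentages use exact rational
arithmetic with half-up rounding to one decimal.

## Bootstrap accuracy and stability

- **Edge-weight accuracy**: B row-resamples with replacement, refit with
  identical settings, percentile CIs with type-7 (linear) interpolation —
  the fixed convention chosen for bit-reproducibility.  A resample with a
  constant column is redrawn and counted.  B = 1000 at study scale.
- **Difference tests**: pair (a,b) of edge weights or node strengths is
  significant when the bootstrap [α/2, 1−α/2] interval of value_a − value_b
  excludes zero.
- **Case-dropping stability**: for each drop proportion q, B subsamples
  without replacement of ⌊(1−q)n⌋ rows are refitted and the subset strength
  vector is Spearman-correlated with the full-sample one (rank correlation,
  because what should be stable is the *order* of strengths).  The **CS
  coefficient** is the largest q — reached through a qualifying prefix of
  the grid — at which P(corr ≥ 0.7) ≥ 0.95, 0 if none qualifies, capped at
  the grid maximum 0.75.
- **Reproducibility**: replicate r of stage s under master seed m uses
  `default_rng([m, s, r, attempt])`, so ensembles are bit-identical across
  runs and independent of worker count or execution order.

Strength centrality is the sum of *absolute* incident edge weights —
signed summation would let negative edges cancel, contradicting magnitude
reports; the signed variant ("expected influence") is available but off by
default.  Ranks break ties by node order.

## Synthetic cohorts

The generator exists so that every stage is testable by parameter recovery
without access to the (undeposited) study data.  Two samplers: exact
enumeration of the 2^p joint for p ≤ 16, and a single-site Gibbs sampler
(fixed scan order, default burn-in 1000 sweeps, thinning 10) for the
65-node emulation; they agree in distribution by chi-square test against
the enumerated pmf.

`generate_cohort` (1) calibrates thresholds by damped per-node
root-finding in logit space until realized marginals (Gibbs-estimated at
n = 10⁴, exact for small p) are within 1.2 percentage points of target;
(2) samples the binary symptom layer; (3) "ordinalizes" each binary state
to instrument-scale raw responses by an exact-inverse construction —
present maps into the above-threshold codes, absent below, reverse items
un-reflected — so dichotomization reproduces the binary layer exactly
(this holds for the stochastic code-jitter variant too, because the jitter
ranges respect the thresholds); (4) injects missing-completely-at-random
gaps at a configurable rate capped at 3.9%, the highest item missingness
observed in the study; and (5) attaches sex (13.7% female), weekly alcohol
units, partner counts, STD flags and VAS values consistent with the
relevant nodes.  The VAS construction is two-point (60/90) with the
below-median code targeted at prevalence 0.40 < 0.5, which makes the
median split exact.

The bundled 65-node specification mirrors the qualitative structure of the
published cohort network: an interconnected depression/anxiety core
bridged to impulsivity, quality-of-life nodes tied to the depression core
through H8, a substance-use block feeding sexual risk, and an adherence
block with internal edges only.  Couplings lie in |β| ∈ [0.5, 1.5]; the
four anchor edges carry the study's reported weights (XT–PR 1.09, OT–PR
1.14, PR–ST 1.44, H8–QV −0.35).  Published prevalences are used as
marginal targets where available (substance use, EQ-5D dimensions, STD);
the remaining targets are fixed, realistic skewed values in 0.03–0.45.

What the generator does **not** emulate: ordinal response distributions
beyond the threshold structure (real Likert data spread over all codes),
item-level measurement error, missingness that depends on symptom status
(real nonresponse is rarely MCAR), and clinical covariates.  Passing
recovery tests therefore shows the estimation machinery is correct under
the model, not that the model is adequate for any particular real cohort.

## Known limitations

- Pseudo-likelihood estimation only; no exact joint-likelihood fit.
- With ~450 candidate cross-block pairs, EBIC at γ = 0.25 with the AND
  rule still admits a small spurious edge in a sizeable fraction of
  samples at n = 4000 (about half, in both this implementation and an
  independent glmnet-based reference).  Perfect recovery of an isolated
  block in ≥ 90% of samples is *not* achievable at these settings; the
  qualitative finding (no systematic adherence connectivity; any
  cross-block edge is tiny, |β| < 0.1) is robust.
- Row-permutation invariance of fits holds to float summation order
  (support exactly, weights to ~1e-12), not bitwise.
- Problem sizes in the validation suite (n = 2000–4000, 12–20 seeds,
  B = 50–100 for the heavier bootstraps) are scaled-down choices that keep
  the full suite runnable on a laptop; study-scale runs use B = 1000.
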