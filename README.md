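# symptomnet

Ising network analysis of mental-health questionnaire data, built for
cohort studies of people living with HIV (PLWH) on antiretroviral therapy:
symptoms of depression and anxiety (HADS), impulsivity (BIS-11), substance
use (MATE-Q part 1b), quality of life (EQ-5D-5L), ART adherence (MMAS-8)
and sexual-risk behaviour, analysed jointly as a 65-node symptom network.

The pipeline is for epidemiologists and network-psychometrics researchers
who want the full chain as tested, scriptable code:

1. **Dichotomization** — per-instrument rules map ordinal item responses to
   symptom present/absent (reverse-keyed items reflected first, sex-specific
   heavy-drinking cut-off, VAS median split), after per-item median
   imputation of missing responses.
2. **Estimation** — an **Ising model** P(x) ∝ exp(Σ τ_i x_i + Σ β_ij x_i x_j)
   over the binary matrix, fitted by **eLASSO**: per node, L1-penalized
   logistic regression of x_i on all other nodes along a 100-point λ grid,
   model selection by the extended BIC
   (EBIC = −2ℓ + k log n + 2γk log(p−1), γ = 0.25), and the **AND rule**
   (both directed coefficients nonzero) for the final edge set.
3. **Centrality** — node **strength**, Σ_j |β_ij|, with ranks.
4. **Accuracy & stability** — bootstrapped edge-weight CIs, bootstrapped
   difference tests for edges and strengths, and case-dropping subset
   bootstrap summarized by the **CS coefficient** (largest case-drop
   proportion keeping the subset-vs-full strength correlation ≥ 0.7 with
   95% probability).

Because cohort data of this kind are rarely shareable, the package ships a
**synthetic-cohort generator** that samples from known Ising ground truth
(exact enumeration for small networks, Gibbs for the 65-node emulation),
calibrates node prevalences to published cohort percentages, and inverts
the dichotomization rules exactly — so every stage is verifiable by
parameter recovery.  See `docs/methods.md` for the model, conventions and
limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
simulated cohort (n = 2000, 2% missingness, seed 7):

```bash
python analysis/01_simulate_cohort.py      # raw responses + ground truth
python analysis/02_build_binary_matrix.py  # impute, dichotomize, prevalences
python analysis/03_fit_network.py          # eLASSO Ising fit
python analysis/04_centrality.py           # strength table
python analysis/05_bootstrap_stability.py  # CIs, difference tests, CS
```

Output of steps 3 and 4 on this cohort:

```
fitted network: 56 edges (truth has 61)
anchor edges (estimate / truth):
  XT-PR: +0.600 / +1.090
  OT-PR: +0.742 / +1.140
  PR-ST: +0.897 / +1.440
  H8-QV: -0.269 / -0.350
top-5 strength centrality:
label  strength  rank
   H8  2.624131     1
   H5  2.615262     2
   PR  2.238859     3
   QP  2.196928     4
   H1  2.021666     5
```

and of step 5 (B = 50 edge bootstrap, B = 25 case-dropping on a coarse
grid):

```
edge CIs: 56 retained edges, replicate mean within CI for 98%
significant edge-weight differences: 431 pairs
significant strength differences: 1157 pairs
CS coefficient: 0.5
```

Reading this: the fit recovers 56 of 61 planted edges with no regard to
block labels; the four "anchor" couplings (ecstasy/other-drug use → multiple
partners → STD, and the depression symptom H8 "slowed down" ↔ perceived
health) are found with the sign and ordering of the ground truth but
shrunken toward zero — the L1 penalty biases retained weights downward at
n = 2000, which is why edge weights from regularized network analyses are
compared within, not across, samples.  H8 ranks most central by strength,
the depression–quality-of-life bridge the method is designed to surface.
Most pairwise differences between edge weights and node strengths are
significant by the bootstrap test, and half the cases can be dropped
before the strength order degrades (CS = 0.5 under this quick, B = 25
configuration; stability summaries sharpen with the study-scale B = 1000).
The separation-guard warnings emitted during resampling concern the rare
self-care node QS (2.7% prevalence), whose coefficients are capped rather
than allowed to diverge in small subsamples.

The same pipeline runs from the command line (`symptomnet simulate`,
`dichotomize`, `fit`, `centrality`, `bootstrap`, `run`, `report`) with a
flat key = value config file; defaults reproduce the study settings
(γ = 0.25, AND rule, B = 1000 bootstrap replicates, one master seed).

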