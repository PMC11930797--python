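# Methods

This note documents the models, conventions and numerical choices behind
`comagraph`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the limits of what the
synthetic cohort can demonstrate.

## Synthetic cohort model

Each subject's node-by-volume series is drawn from a zero-mean
multivariate normal with block covariance
$\Sigma = (1-c\rho_w)I + c(\rho_w-\rho_b)B + c\rho_b\mathbf{1}\mathbf{1}^T$,
where $B$ is the block-diagonal indicator of module membership (contiguous,
near-equal blocks), $\rho_w$ and $\rho_b$ are the within- and
between-module correlations, and $c$ is a global coupling multiplier
applied to all off-diagonal covariance. Each of the three summands is
positive semi-definite whenever $0 \le \rho_b \le \rho_w$, $c\rho_w \le 1$,
so the model is valid on its whole admissible parameter range; the
constructor still verifies the smallest eigenvalue and rejects anything
below $-10^{-10}$. Observation noise is additive i.i.d. Gaussian — the
simplest perturbation that attenuates correlations without changing their
structure. Sampling goes through one Cholesky factor per group and a
per-cohort `numpy` Generator, so the entire cohort is a pure function of
the configuration, including its seed.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_good` / `n_poor` | 44 / 26 | reference cohort composition |
| `n_nodes` | 264 | standard 264-region functional parcellation |
| `n_volumes` | 220 | typical ~8-minute resting-state acquisition |
| `n_modules` | 8 | order of magnitude of canonical resting-state systems |
| `rho_within` / `rho_between` | 0.6 / 0.2 | clear modular contrast, comfortably inside the PSD region |
| `coupling_good` / `coupling_poor` | 0.9 / 0.5 | strong global-coupling deficit in the poor-outcome group |
| `noise_sd` | 0.5 | attenuates empirical correlations to a realistic range without masking structure |

Outcome-linked labels: EEG category (five classes: suppressed; suppressed
background with pathological bursts/GPDs; continuous; epileptiform;
discontinuous/heterogeneous burst suppression) is drawn from
outcome-conditional multinomials chosen so that continuous activity
dominates good outcome and malignant patterns are enriched in poor
outcome; the implied marginal counts in a 44/26 cohort approximate the
observed distribution across the four commonly populated classes
(≈ 9/30/7/14). The guideline EEG class (good/poor/indifferent) is derived
from the category (continuous → good with probability 0.7; suppressed
patterns → poor with probability 0.7; otherwise indifferent). The
pupil/SSEP indicator is Bernoulli(0.02) in good and Bernoulli(0.45) in
poor outcome — essentially a specificity-one predictor, as it is
clinically. Covariates: arrest-to-MRI hours Normal(59, 21) good /
Normal(66, 27) poor, hospital uniform over three sites, comatose-during-
MRI Bernoulli(0.36 / 0.96) by group. The linkage strengths are free
parameters of the generator, not estimates: no quantitative EEG-to-
connectivity mapping is available to fit them.

What the generator deliberately omits: BOLD hemodynamics, autocorrelation
in time, scanner drift, head motion, physiological noise, spatial
geometry of parcels. Tests passing on this cohort therefore demonstrate
the correctness and calibration of the *analysis* — not robustness of the
measures to fMRI artefacts, which is upstream preprocessing's job.

## Connectivity

Series are mean-centred and unit-scaled per node before Pearson
correlation; a zero-variance node is a hard error naming the node, since a
constant series indicates a degenerate extraction. Correlations are
clipped to $[-1, 1]$ against floating-point drift; an off-diagonal
$|r|=1$ is rejected (infinite Fisher z — duplicated series). Fisher
transform, negative-edge zeroing and a zero diagonal produce the single
matrix representation used everywhere downstream.

Two conventions the source analysis leaves open are fixed as follows and
exposed as switches:

- **Positive-edge mean.** Whole-brain FC divides by the number of strictly
  positive edges (the literal reading of "average of all positive edges");
  `include_zeros=True` divides by all $N(N-1)/2$ pairs instead.
- **Nodewise connectivity** is computed on the normalized (Fisher-z,
  negatives-zeroed) matrix with an $N-1$ denominator, zeros included —
  one representation throughout, rather than a second raw-r pathway.

An optional discard-first-k switch (default 5 on the synthetic path) mimics
dropped pre-steady-state volumes; bandpass filtering and nuisance
regression are upstream of this package's boundary.

## Graph measures

Thresholding keeps exactly $k=\lfloor d\,N(N-1)/2+0.5\rfloor$ edges,
weights intact (binarization is a flag, off by default, matching the
weighted metric formulas). Ties at the cutoff break deterministically by
(weight descending, upper-triangle index ascending) so results are
platform-independent. Requesting more edges than exist keeps all nonzero
edges and warns.

- **Clustering**: Onnela form, $C_i = \frac{1}{k_i(k_i-1)}\sum_{jh}
  (\tilde w_{ij}\tilde w_{ih}\tilde w_{jh})^{1/3}$ with weights rescaled
  by the global maximum, so $C\in[0,1]$; degree-<2 nodes contribute 0.
- **Global efficiency**: edge length $1/w$, Dijkstra all-pairs shortest
  paths, mean of $1/d_{ij}$ with disconnected pairs contributing 0.
- **Modularity**: Newman–Girvan weighted $Q$ at resolution $\gamma$
  (default 1), maximized by Louvain with 100 seeded restarts (default) and
  best-$Q$ selection. Two refinements make the optimizer reliable on the
  graph sizes where it can be checked exhaustively: odd-numbered restarts
  start from a random coarse partition rather than singletons (escaping
  the shared basin the greedy singleton start falls into), and every
  candidate partition is polished by alternating single-node moves
  (detaching allowed) with whole-community merges until neither improves
  $Q$. With these, the returned $Q$ matches exhaustive partition
  enumeration on random graphs of ≤ 8 nodes to $10^{-9}$.
- **AUC surrogate**: trapezoidal integral of the metric over the density
  grid, divided by the grid span, so a constant curve returns its constant
  and the surrogate lives on the metric's own scale.

## Statistics

Test routing is deterministic and logged: Shapiro-Wilk at α = 0.05 in each
group routes continuous variables to Student's pooled-variance t (both
normal) or Mann-Whitney U; categorical tables use chi-square without
continuity correction, with Fisher's exact fallback when any expected cell
is below 5. Cohen's d is the classical pooled-(n−1)-SD form on unadjusted
values. The covariate-adjusted contrast is a maximum-likelihood logistic
model of outcome on the measure plus arrest-to-MRI hours, hospital
indicators and the comatose flag, reporting the Wald p for the measure;
rank-deficient designs and separation raise explicit diagnostics rather
than returning numbers. Benjamini–Hochberg FDR is applied where the
analysis plan applies it — across the four measure comparisons and across
pairwise EEG contrasts — while nodewise correlations are reported
uncorrected at p < .05/.01/.001 by design. Outcome is coded good = 1 in
the nodewise correlation, so positive r means higher connectivity with
good outcome. Note that BH re-adjustment is not generally idempotent;
what holds, and what the tests assert, is that tied (flat) adjusted
vectors are fixed points and re-adjustment never lowers a value.

## Prediction

Poor outcome is the modelled event. The guideline design is an intercept,
the combined pupils/SSEP indicator (combined because the criterion is
"and/or"; a split entry is a trivial design change), and two EEG-class
indicators against the indifferent reference. Augmented models append one
graph measure, keeping the nested structure for the likelihood-ratio test
(2Δℓ against χ² with df = added parameters). Evaluation is in-sample,
matching the analysis being reproduced: ROC over all score thresholds with
tied scores grouped, trapezoidal AUC, and the two clinical operating
points — maximum sensitivity for good outcome among points with
specificity ≥ 0.90 (score re-poled so good is positive) and for poor
outcome at specificity 1.00. The predict-nobody point always qualifies, so
an uninformative model scores sensitivity 0 rather than erroring.

Separation handling: with a near-specificity-one predictor and ~70
subjects, quasi-separation (an empty predictor-outcome cell) is common.
Newton then fails to converge because the affected coefficient diverges,
and the fit falls back to a ridge-penalized logistic regression
(L2 penalty 1.0, documented in the result as `penalized`). The LRT is
only reported when both nested fits are genuine ML fits; for penalized
pairs, the ridge objective (log-likelihood minus penalty) is the monotone
comparison, since a nested model can never outscore its superset under the
same penalty.

## Simulation scales and calibration

Problem sizes used by the automated studies are chosen to exercise the
full pipeline at desk scale:

- **Oracle suite**: 200 random graphs of 4–8 nodes — small enough for
  exhaustive partition enumeration (≤ 4140 partitions) and O(N³) triangle
  and Floyd-Warshall oracles.
- **Null calibration**: 1000 cohorts of 50 + 50 subjects, 16 nodes, 60
  volumes, equal couplings. Group sizes of 50 keep the Wald, Kruskal-
  Wallis and LRT chi-square approximations in their nominal regime: at
  very small n (e.g. 12 per group) those approximations are themselves
  conservative or mildly inflated, which would test the asymptotics, not
  the implementation. The LRT tally uses the replicates where both nested
  ML fits exist (about 60 %; quasi-separation rightly voids the rest).
- **Coupling contrast**: 100 cohorts of 44 + 26 subjects, 24 nodes, 120
  volumes, couplings 0.9 vs 0.5 — the direction checks (median FC higher
  in good outcome, FC–clustering r > 0.7, fit improvement under
  augmentation) are scale-free in nodes.

## Known limitations

- Patient-level values from the original cohort (medians, specific AUCs,
  node counts) depend on undeposited clinical data and are outside what a
  synthetic cohort can or should reproduce; the pipeline reproduces the
  analysis's structure, calibration and qualitative behaviour.
- The generator's temporal independence means effective sample sizes per
  subject are larger than in autocorrelated BOLD data; empirical
  correlations are correspondingly less variable.
- In-sample (apparent) AUC and sensitivities are optimistic by
  construction; an optimism-corrected bootstrap is a natural extension but
  is not part of the reproduced analysis.
- Louvain's global-optimality is only verifiable exhaustively at toy
  sizes; at 264 nodes the restart/refinement scheme is a heuristic, as it
  is in every connectome toolbox.
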