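# clamtrace

Stepwise geographical-origin authentication of the Manila clam
(*Ruditapes philippinarum*) from stable-isotope and fatty-acid chemistry.

## The problem

Manila clams are a high-value bivalve whose domestic (Korean) product
commands a premium over imports, which makes origin fraud attractive —
and, because most clams in Korean waters now grow from imported Chinese
seed, genetic markers no longer distinguish where a clam was actually
grown. Habitat chemistry does: bulk tissue δ13C/δ15N record the local
dietary organic matter and nitrogen baseline, the relative composition of
phospholipid fatty acids (FAs) records the local plankton community, and
the carbon isotope ratios of individual FAs (compound-specific isotope
analysis, CSIA) record carbon sources with compound-level resolution.

These assays differ enormously in cost. `clamtrace` implements a tiered
("stepwise") protocol that spends the expensive assays only where the
cheap ones fail: every sample is first classified from bulk δ13C/δ15N;
samples that are not authenticated are escalated to the 15-FA relative
profile, and then to δ13C of six individual FAs.

## The model

Each tier is a linear discriminant analysis (LDA) on min–max-scaled
features, evaluated by leave-one-out cross-validation (LOOCV):

- δ-notation, per mil vs reference (VPDB for C, air N2 for N):
  δ = (R_sample/R_standard − 1) × 1000;
- feature scaling: x′ = (x − min A)/(max A − min A), so every feature
  lies in [0, 1];
- LDA: shared-covariance Gaussian classifier; class k scores
  δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + log π_k with pooled within-class
  covariance Σ (divisor N − K) and priors π_k; up to min(K − 1, p)
  discriminant axes from the between- vs within-class generalized
  eigenproblem;
- LOOCV: n refits, each excluding one sample; held-out predictions pool
  into a confusion matrix from which per-class and overall prediction
  rates are reported;
- routing: classes whose per-class LOOCV rate falls below a threshold
  (default 100%) escalate to the next tier, optionally subsampled to k
  clams per site (k = 3 reproduces the triplicate design: 17 sites × 3 =
  51 escalated samples). A strict per-sample policy (escalate exactly the
  misclassified clams) is also provided.

The raw per-clam measurements behind the published study are not public,
so the package ships the published site-level summaries (mean ± SD and n
per site) as fixtures and a seeded generator that draws synthetic
per-sample datasets from them: Gaussian per feature, Dirichlet for the
15-FA composition (nonnegative, sums to 100%).

## Worked example

```
$ clamtrace cascade --seed 1 --out-dir demo/
tier dual_isotope: cohort 102, overall 64.7%
tier fa_profile: cohort 51, overall 100.0%
```

102 synthetic Korean clams (17 sites, 4 coastal provinces) enter tier 1.
Bulk δ13C/δ15N authenticates 64.70% of them under LOOCV — no province
reaches 100%, so all 17 sites escalate triplicates (51 clams) to the FA
tier, which separates the four provinces completely and short-circuits
the third (CSIA) tier. `demo/stepwise_summary.csv` holds the per-class
ledger — each cell is "cohort (LOOCV-correct)":

```
region,dual_isotope,fa_profile
CC,25 (21),15 (15)
GN,26 (17),12 (12)
JB,25 (16),12 (12)
JN,26 (12),12 (12)
Total (Cross-Val)%,64.70%,100.00%
```

with per-tier confusion matrices (`confusion_dual_isotope.csv`, …), the
per-sample routing ledger, LD projections and a JSON run report alongside.
The library surface mirrors this: `builtin_fixtures` / `generate_samples`,
`fit_scaler` / `apply_scaler`, `fit_lda` / `predict` / `project` / `loocv`,
`route_unauthenticated` / `run_cascade` / `prediction_rates`.

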