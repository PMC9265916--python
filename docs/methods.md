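# Methods

## Scope and data model

`clamtrace` models a stepwise origin-authentication protocol for Manila
clams sampled from 17 Korean sites in four coastal provinces (CC = 25,
JB = 25, JN = 26, GN = 26 clams; 102 total), plus imported lots from
China (n = 15) and DPR Korea (n = 16). A sample is a row of features:
bulk δ13C (‰ vs VPDB), bulk δ15N (‰ vs air N2), the relative percent of
15 phospholipid fatty acids, and δ13C of up to six individual FAs.

The per-clam measurements behind the study are unpublished; the package
therefore carries the published **site-level** summaries verbatim —
per-site mean ± SD and n for bulk isotopes (17 sites), for δ13C-FA
(17 sites × 6 FAs, triplicates), and country-level bulk isotopes — and
generates per-sample data from them.

## Synthetic-data generator

Within a site, each Gaussian feature is drawn independently from
N(mean, SD²). Only marginal mean ± SD are published, so no between-assay
covariance exists to honour; generated data therefore lack the
within-clam correlation structure (e.g. between δ13C and δ13C-16:0) that
real tissue would show, and passing tests demonstrate correct pipeline
behaviour under the published marginals, not classifier performance on
real clams. An SD of 0 degenerates to the exact mean.

FA compositions are drawn per sample from a Dirichlet with parameters
`fa_dispersion × composition`, which guarantees nonnegativity and unit
sum and mean-centres on the site profile; draws are rescaled to percent.
The default dispersion of 500 puts the SD of a 25% component near 2
percentage points, the scale of assay repeatability for major FAs.

The per-site 15-FA compositions are **constructed, not transcribed**:
the published text names the biomarker FAs and gives only class-level
ranges. The fixed panel is 14:0, 15:0, 16:0, 17:0, 18:0 (SFA); 16:1n-7,
18:1n-7, 18:1n-9, 20:1n-7, 20:1n-9 (MUFA); 18:2n-6, 18:3n-3, 20:4n-6,
20:5n-3, 22:6n-3 (PUFA) — 14:0 is an assumption completing the
five-SFA panel, the other fourteen are named in the source material.
Regional templates respect the published constraints (SFA within
26.20–65.48% and PUFA within 10.23–32.33% of total FA; DHA/EPA > 1 in
GN; diatom markers elevated in CC and China; bacterial markers in JB;
highest MUFA in DPR Korea); sites within a region get small
deterministic 16:0↔18:0 and EPA↔DHA trades so they are distinguishable.
These profiles make the FA tier strongly informative by construction —
which matches the reported outcome of that tier, but is an assumption,
not an estimate.

All randomness flows through one `numpy.random.default_rng(seed)` per
`generate_samples` call; seeds are explicit arguments everywhere, never
global state.

## δ notation

δ = (R_sample/R_standard − 1) × 1000 and its algebraic inverse
R = R_standard(1 + δ/1000); δ ≤ −1000‰ is rejected as nonphysical. The
round trip is exact to 1e-12 over (−900, 900) ‰. δ values carry
element/reference metadata and refuse mixed-reference arithmetic, since
carbon (VPDB) and nitrogen (air-N2) scales are not commensurable.

## Scaling

Min–max scaling is fit column-wise and remembered (`ScalingParams`,
JSON-serializable for provenance). Design choices:

- **Constant columns** map to 0 with a warning rather than NaN: the
  column carries no discriminant information either way, and finiteness
  keeps LDA defined.
- **Held-out samples** outside the training range are returned as
  computed (possibly outside [0, 1]) and counted in a warning; clipping
  would silently move points toward the training hull.
- **Fold policy.** The default (`prefit`) fits the scaler once on the
  full dataset before LOOCV, mirroring a normalize-then-cross-validate
  order; `per_fold` refits inside each fold and is the leakage-free
  variant. Both are exposed because the protocol's leakage control is
  not specified; with 1–2 features and n ≥ 51 the difference is small.

## LDA

Hand-written shared-covariance Gaussian discriminant (no quadratic
variant). Pooled covariance uses divisor N − K. If its condition number
exceeds 1e10, a ridge λI with λ = 1e-8·trace(Σ)/p is added — triplicate
sites make near-singular pooled covariances routine. Priors default to
class frequencies (`proportional`), the common default of R-style LDA;
`uniform` is available since the study never states priors. Posteriors
are the softmax of the discriminant scores; exact ties break to the
lexicographically earliest class and are logged. Discriminant axes solve
`eigh(S_between, S_pooled)`; exactly min(K − 1, p) axes are returned
with nonincreasing eigenvalues, and projection subtracts the
prior-weighted grand mean so it maps to the origin.

Correctness is pinned by two independent oracles in the test suite: a
direct `multivariate_normal.logpdf + log prior` argmax on random small
instances (exact agreement), and scikit-learn's
`LinearDiscriminantAnalysis` (means, predictions, posteriors to 1e-6).
Neither is a runtime dependency.

## LOOCV and reporting

LOOCV requires ≥ 3 samples per class so every training fold keeps ≥ 2.
Confusion matrices are true-row/predicted-column. Per-class prediction
rates are reported half-up to one decimal; pooled totals are truncated
(rounded toward zero) to two decimals — both computed in exact rational
arithmetic from the integer counts, so printed rates are independent of
binary float representation.

## Cascade

Tiers are evaluated in order; each tier's LOOCV runs on its cohort.
Routing policies:

- `site_rate_below` (default, τ = 100%): every sample of a class whose
  per-class rate is below τ escalates; with `subsample_k = 3` the first
  three samples per site (by sample id) are escalated — the triplicate
  design that yields 51 of 102 Korean clams when all provinces are
  unresolved.
- `sample_misclassified`: exactly the LOOCV errors escalate.

Both are provided because the published selection rule is internally
ambiguous (triplicates were taken from all 17 sites, including the
best-classified province). Samples whose class was flagged but which
were not in the escalated subsample finalize at the current tier with
status `unescalated`. At the final tier every remaining sample takes its
LOOCV-predicted label; no "unresolved" end state exists, since the
protocol defines none. The ledger assigns every input exactly one final
tier, status and label.

`mode="parallel"` freezes the cohort after tier-1 routing and evaluates
each later tier on that same cohort independently — the reporting
arithmetic used when one escalated subsample is assayed by each richer
method separately (e.g. the 57-sample three-country summary: 51 KOR +
3 CHN + 3 NK evaluated by both the FA and the CSIA tier).

## Numerical and degenerate-input choices

- Rates: exact `Fraction`/`Decimal` arithmetic before rounding.
- Weighted fixture averages are computed from the printed decimals as
  exact rationals, so half-way cases round deterministically.
- `subsample_k` larger than a site's routed count takes all and logs a
  notice; τ outside (0, 100] and unknown policies/modes raise.
- A routed sample missing a later-tier feature raises an error naming
  the sample and feature.

## Problem sizes used in tests and the acceptance script

Simulations run at the study's own sizes (102 Korean clams, 133 for the
three-country analysis) over 10 seeds, the null-separation control at
n = 100 over 20 seeds, and moment-recovery checks at n = 10,000 for a
single site; the full suite and the acceptance script each complete in
well under a minute.

## Known limitations

- No within-site covariance between features, no seasonal or
  environmental (POM/DIN baseline) structure, and no concentration data
  — the generator emulates the published marginals only.
- The FA-tier separability is assumed via the constructed profiles, so
  the cascade's tier-2 performance on synthetic data validates plumbing
  and routing, not the biological claim.
- Published confusion counts cannot be regenerated without the raw
  data; they are bundled as reference inputs and only the arithmetic
  derived from them is reproduced exactly.
- No stepwise feature selection, PLS-DA/ensemble alternatives, figure
  styling, or single-model fusion of all feature blocks.
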