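# Methods

## Problem setting

A single-table clinical dataset with categorical and numeric columns, a
binary outcome (target), and deterministic logical rules of the form
"trigger column = trigger value ⇒ dependent column = required value".
Missing values are refused at load time: the method assumes a complete table
(registry analyses exclude incomplete records upstream), and imputation
would fabricate clinical facts.  The second listed target category is the
positive/event class by convention.

## Association analysis

Cramér V is computed from the Pearson chi-square of the contingency table,
`V = sqrt(chi2 / (N * min(r-1, c-1)))`, without Yates continuity correction
and without bias correction — the classical definition, because V = 1 must
mean *exact* functional dependence here, and bias-corrected variants can
return values below 1 on deterministically linked finite samples.
Zero-count categories are dropped before fixing r and c (otherwise an
unobserved category inflates `min(r-1, c-1)` and deflates V).  A column with
a single observed category gets V = 0 against every partner: no association
is measurable against a constant, and defining it away avoids spurious
division criteria.

Numeric columns enter after equal-frequency (quantile) binning with a
**point-mass carve-out**: any single value occupying at least 1/n_bins of
the rows receives a dedicated bin before the remaining values are
quantile-binned.  The carve-out matters: a structural zero (pack-years of
non-smokers) smeared into a quantile bin together with small positive values
destroys the exact row purity of the contingency table, and the
deterministic pair no longer scores V = 1.  Default `n_bins = 10`; the
binner is fit on one column and reusable on another so that real and
synthetic data share bin edges in fidelity scoring.

Division pairs are column pairs (target excluded) with `V >= 1 - 1e-9`; the
tolerance absorbs floating-point noise in the chi-square accumulation and is
configurable.  The *main attribute* of a pair — the division feature — is
the member with fewer observed distinct values, ties broken toward the
natively categorical member, then lexicographically.

## Partitioning

The table is cross-partitioned by outcome class first, then by each division
feature.  The class split is never dropped; a division-feature split that
would leave any subset of a class branch below `min_subset_size` (default
50) is dropped *for that branch* and logged, because over-division starves
the per-subset generators of training rows.  The partition is an exact
cover: subsets are pairwise disjoint, labels are unique, and the multiset of
rows equals the input.  Multiple V = 1 pairs produce nested cross-splits in
descending-V order; the guard bounds the fragmentation.

## Gaussian-copula reference backend

Per column the fit stores an empirical marginal — sorted training values for
numerics, category frequencies mapped to contiguous sub-intervals of [0, 1]
for categoricals — and per table a correlation matrix of normal scores
(numerics: `Phi^-1((rank - 0.5)/n)`; categoricals: `Phi^-1` of the interval
midpoint).  Undefined correlations from constant columns are set to 0 and
the matrix is repaired to the nearest positive-semidefinite correlation
matrix by eigenvalue clipping.  Sampling draws multivariate normals, maps
through the standard normal CDF, and inverts each marginal: numerics by
linear interpolation between sorted training values (output therefore
confined to the training min/max — intentional, this is what reproduces
structural zeros exactly), categoricals by locating u in the cumulative
frequency intervals.  A one-row subset degenerates to row replication with a
logged warning.  All sampling is driven by a seeded generator;
identical seeds give identical outputs, and per-subset seeds are derived
from the run seed via a seed sequence.

The `independent` backend is the same machinery with an identity dependence
matrix — an ablation that preserves marginals but destroys pair trends, used
to demonstrate that the copula's dependence modelling contributes.

Neural tabular GANs (CTGAN, CopulaGAN) attach through the same
`fit`/`sample` contract via `register_backend`, declaring a hyperparameter
grid (e.g. training epochs 100–500); `dcsdg sweep` evaluates each grid point
by overall fidelity on a held-out real split.  Their training internals are
out of scope; the reference backends have empty grids.

## Generation strategies

* **dc** — association matrix → division pairs → partition → per-subset
  fit/sample → conquer (concatenate + seeded shuffle).  The requested volume
  is first split across classes by the class ratio — minority count
  `round(total * w_min / (w_min + w_max))`, so 1:100 at total 5000 gives 50
  event rows — then within a class proportionally to the subsets' original
  sizes with largest-remainder rounding, which conserves the total exactly.
  The proportional-within-class rule is this package's choice; any split of
  the class volume across its subsets is compatible with the method.
* **cs** — one backend fit on the whole table; batches are sampled and rows
  violating any logical rule discarded until the target count accumulates.
  If `max_batches` batches do not suffice, the run fails with the measured
  acceptance rate (the information-loss failure mode of filtering).
* **none** — one backend fit on the whole table, plain sampling; the
  unconstrained arm that demonstrates rule violations.

Class-ratio control applies to the dc strategy, where the partition exposes
per-class subsets; cs and none sample from a whole-table fit and inherit the
training prevalence.

## Fidelity and consistency metrics

Column shapes: 1 − KSS (sup-distance of empirical CDFs, merge-sweep over
pooled values) for numerics; 1 − TVD (half-L1 between PMFs over the union of
categories) for categoricals.  Pair trends: numeric-numeric pairs score
`1 − |ρ_real − ρ_syn| / 2` with Pearson ρ; this resolves an ambiguity in the
source material, which describes the computation as an "absolute squared
difference" while also requiring a 0–1 score with 1 = identical — the
halved absolute difference is the standard quality-report convention that
matches the stated range, and is recorded here as an interpretation.  Every
other pair (categorical members, or a numeric constant in either table, for
which correlation is undefined) is scored by contingency similarity —
1 − half-L1 between joint cell proportions — with numeric members
discretized by bins fitted on the real column and applied to both sides.
Shape, pair-trend and overall scores are arithmetic means (of column scores,
pair scores, and the two aggregates respectively); the CLI prints them ×100.

A row violates a logical rule iff the trigger matches and the dependent
value differs from the required constant; numeric equality uses absolute
tolerance 1e−9, large enough for representation noise and far below any
clinically meaningful difference.

## TSTR utility protocol

Stratified split (default 70/30, per-class rounding); features one-hot
encoded over the *schema* categories so train and validation matrices align
regardless of realized categories; AUC by the Mann-Whitney rank statistic
(equivalent to trapezoidal ROC area, ties worth 1/2); F1 macro-averaged over
the two classes at threshold 0.5 with the undefined-as-0 convention.  Macro
rather than event-class F1 because the imbalanced-arm behaviour it produces
(F1 collapsing toward the majority-only value while AUC stays moderate)
matches how such results are conventionally reported; event-class averaging
is available via `f1_average="positive"`.  Mean/SD over repeated seeds use
the population (n-divisor) SD.  Classifier adapters carry fixed small
hyperparameters: decision tree depth 6, random forest 100 trees, XGBoost 100
rounds at depth 4 and learning rate 0.1, LightGBM 100 rounds — strong enough
to recover most of the planted signal, cheap enough for repeated-seed runs
on one CPU.

## The fixture generator

Emulates the statistical structure the method assumes: binary outcome with
prevalence 0.5 by default (presets: `nsclc-like` n = 2304, `small` n = 400,
`imbalanced-od` prevalence 0.1); smoking status with class-dependent rates
(0.35 controls, 0.65 events); pack-years exactly 0 for non-smokers and
log-normal (location 3.2, scale 0.5 — median ≈ 25 pack-years, strictly
positive) for smokers; three clinical feature analogues (age, FVC, DLCO)
with within-class correlation (FVC–DLCO 0.6, age–lung-function −0.4, the
kind of dependence pair-trend preservation must be tested on) and
event-class mean shifts of +1.0, −1.1, −1.1 SD; plus independent numeric
and categorical noise columns.  Draws are retried until every
class × smoker cell is populated, so the four-subset division always
exists.

The truth record includes the closed-form Bayes AUC: the Gaussian block's
log-likelihood ratio is normal with Mahalanobis separation
`delta² = d' R^-1 d`, smoking status adds discrete log-likelihood offsets,
and the optimal AUC is the mixture over (case, control) smoker-status pairs
of `Phi((delta² + lam_case − lam_ctrl) / sqrt(2 delta²))`.  Default effects
put it at 0.850, comparable to strong tree ensembles on real registry
mortality tables, which keeps TSTR comparisons meaningful.  Pack-years adds
no signal beyond smoking status by construction (its conditional
distribution is class-independent).

What the fixture does *not* emulate: real marginal shapes (skewed labs,
heaped self-reports), measurement error, label noise, rare categories,
or columns correlated with the noise block.  Tests passing on the fixture
show the mechanisms work — exact rule preservation, division recovery,
dependence recovery, the balanced-vs-imbalanced ordering — not that fidelity
or utility numbers transfer to any particular real dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run the association/division stage at
n = 1616 (the development-cohort scale), generation at the standard volume
5000, metric-oracle comparisons on 200 random instances each, and
repeated-seed protocols with 5 seeds — sizes at which every stochastic check
has comfortable margin on a single CPU.  Numeric edge cases: CSV numerics
are written in shortest round-trip form and parsed with correctly-rounded
conversion so read(write(d)) is value-identical; V is clamped to [0, 1]
against floating-point overshoot; the copula's normal-score transform clips
u to [1e−12, 1 − 1e−12] before the inverse CDF.

## Known limitations

Only single-table data, no dates or free text; rules are single-trigger
equality constraints (no compound or inequality conditions); the reference
copula cannot extrapolate beyond training ranges and models dependence only
through rank correlation; multiple division criteria multiply subsets and
can starve the per-subset fits (mitigated, not solved, by the
`min_subset_size` guard); cs/none strategies do not control class balance.
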