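# Methods

## Data model

A `CtMatrix` is an assays × samples table of cycle-threshold values with
an explicit missing mask and a stage tag that can only advance through
`raw → filtered → normalized → imputed → shrunk`. The sign convention is
fixed throughout the package: lower Ct means higher expression, one Ct
unit is a two-fold abundance difference at perfect probe efficiency, and
effects are always stated on the Ct scale (an assay "up" in the
mutation-carrier group has a *negative* Ct shift there).

## Preprocessing

**Detection filter.** An assay is excluded iff the fraction of samples
with a missing Ct or Ct > `max_ct` (default 35) is ≥ `max_missing_frac`
(default 0.20) — the boundary case excludes. In retained assays,
cells above `max_ct` are set to missing and later imputed: lateness and
missingness are treated as one badness criterion, so a late well should
not survive as a (noisy, censored-range) number. This censor-then-impute
ordering is a declared choice; filtering precedes normalization.

**Lowess normalization.** The reference profile is the per-assay median
across samples — robust to the 8-vs-32 imbalance and to the handful of
genuinely differential assays. For each sample the deviation
(sample − reference) is lowess-smoothed against the reference Ct
(`statsmodels` lowess, span 2/3, the classic default) and the fitted
deviation is subtracted. Missing cells stay missing; a sample with fewer
than 10 observed values cannot support a fit and is an error.

**KNN imputation.** A missing cell (assay a, sample s) is replaced by
the unweighted mean, over the `k` = 10 assays nearest to a, of their
values in s. Distance is Euclidean over the samples where both assays
are observed, scaled by the shared-sample count
(`sqrt(Σd²/n_shared)`) so that assays with different missingness
patterns are comparable; candidate neighbours must themselves be
observed in s, ties in distance break by row order, and fills are always
computed from originally observed values (an imputed cell never feeds a
later imputation). Fewer than k eligible neighbours downgrades to all of
them with a warning; zero is an error.

**Shrinkage of extremes.** Per assay, values outside
median ± `c`·1.4826·MAD (default c = 3) are clamped to the bound —
winsorization, the mildest reading of pulling extremes toward the
center. An assay with MAD = 0 (majority-constant) is left unchanged
rather than collapsed. The operation is idempotent.

## Differential expression

Nominal inference is a pooled-variance two-sample t-test per assay
(Welch optional). Zero pooled variance is degenerate: equal means give
(t=0, p=1), unequal means a signed infinite t with p = 0 and a logged
flag.

**Westfall–Young step-down min-P.** Group labels are permuted B times
(default 1000) by a seeded generator; when B meets or exceeds the number
of distinct label assignments C(n, n₁), all assignments are enumerated
instead (a 2-vs-2 design has only 6). For every relabelling the full
vector of *analytic* t-distribution p-values is computed; assays are
ordered by observed p ascending (ties broken by assay id), successive
minima over ranks i..m give each relabelling's q(i), and the adjusted
p(i) is the share of relabellings with q(i) at or below the observed
p(i), monotonized to be non-decreasing. The observed (identity)
labelling is always a member of the reference set — one of the
enumerated assignments in exhaustive mode, prepended to the shuffles
otherwise — which is equivalent to the bias-protected (1+count)/(1+B)
estimator and guarantees no adjusted p is 0.

Two numerical points matter here. First, using the t-distribution
transform per relabelling (rather than a within-assay permutation rank)
is what makes min-P workable when B is modest relative to the number of
assays: rank-based permutation p-values live on a 1/(B+1) grid, and with
hundreds of assays the null distribution of their minimum saturates at
the grid floor, leaving the procedure unable to resolve the 5% quantile
(degenerating to all-or-nothing rejections depending on how the
observed side is counted). The analytic transform is the standard
continuous within-assay standardization for equal-df designs and is
consistent with t-tests supplying the nominal p-values. Second,
comparisons use a 1e-15 absolute guard so the identity column always
counts against itself despite scalar-vs-vectorized float paths.

**Overall P** is the adjusted p of the top-ranked assay — equivalently
the single-step global min-P test: the probability under label
permutation that the family's minimum p-value is at least as small as
observed.

**Empirical q-values** use the permutation p-value matrix (identity
column excluded) as the null: q(p) = [mean over relabellings of the
count of null p ≤ p] / [count of observed p ≤ p], capped at 1 and
monotonized by a cumulative minimum from the largest observed p
downward. π₀ is fixed at 1, the conservative choice.

Candidates are the assays with nominal p < α (default 0.05), ordered by
p, annotated with direction ("up" = lower Ct in group 1).

## qRT-PCR validation

Duplicate wells agreeing within 2 cycles are averaged; a pair differing
by strictly more than 2 keeps the well nearer (absolute difference) to
the assay's center, operationalized as the median of all that assay's
wells across samples. ΔCt subtracts the endogenous-control Ct (RNU48)
per sample, making values invariant to sample-level loading shifts;
−ΔCt is the log₂ expression proxy. Group comparison is a pooled t-test
on −ΔCt; the mean difference d and its CI are exponentiated base 2, so
log₂(FC) = d exactly by construction. An assay is flagged undetectable
when its median reconciled Ct exceeds 35 (low abundance crosses the
threshold late) or more than half its samples are missing; the
detection-limit reading is the biologically coherent one (high Ct ⇒
poor detection). Validation p-values are reported unadjusted.

## Target integration

Genes qualify when some probeset is down-regulated with p < α (strict)
in *each* tissue table — the any-probeset collapse, the natural rule
when a probeset-level selection must be reported at gene level. The
qualifying set is intersected with the candidate miRNAs' predicted
target lists (gene symbols upper-cased on ingest); the result maps each
gene to exactly the candidates predicting it and tallies genes by that
multiplicity. Family members with shared seed sequences (e.g.
miR-548b-5p / miR-548c-5p) are distinct candidates. Pathway enrichment
is out of scope; the gene list is exported for external tools.

## Synthetic data

The array generator emulates the study design: 664 assays × 40 samples
(8 carriers, all pathology type 1, vs 32 non-carriers spanning types
1–3), per-assay baselines N(28, 3²) Ct, per-sample shifts N(0, 0.5²)
(removed by normalization), well noise N(0, 0.6²), and 20 truly
differential assays with shifts drawn from [0.5, 2] Ct, signs split
evenly. Dropout is expression-dependent, not MCAR: a well is missing
with probability `1/(1+exp(−(ct−34)/1.5))`, a logistic in its latent Ct,
because the detection filter couples missingness and late Ct. The slope
1.5 Ct was chosen to make dropout negligible below ~30 Ct and heavy
beyond the censoring threshold; with these defaults roughly 580–610 of
664 assays pass the filter. The published pass rate for this assay
panel was lower (490/664), but the raw arrays' missingness profile is
unpublished, so the generator is calibrated for plausibility, not for
matching that count; no acceptance quantity depends on it.

The qPCR plate generator yields two wells per sample × assay with
shared latent value and independent technical noise; with a configured
outlier rate one well is displaced upward by > 2.5 cycles — the
one-sided, single-well mechanism that is minimal to trigger the
reconciliation rule. The endogenous control never carries a group
effect. The integration fixture generator plants candidate genes as
significantly down in both tissues and surrounds them with decoy genes
each failing exactly one selection filter (down in one tissue only, up,
non-significant, or untargeted).

What the generators do *not* emulate: pre-amplification chemistry,
probe efficiencies ≠ 2, RNA-quality (RIN) effects, correlated
co-regulation between miRNAs, or array-position effects. Passing tests
therefore demonstrate the statistics are implemented and calibrated
correctly under idealized noise, not that the pipeline is robust to
every real-data pathology.

## Problem sizes in the test suite

The suite favours many small seeded replicates over few large ones:
family-wise error is checked on 200 null datasets of 100 complete-data
assays at B = 200 (complete data, because FWER is a property of the
test, not of the imputation path); planted-effect recovery runs the full
preprocessing and testing chain on 25 study-sized (664 × 40) replicates
with effects ≥ 1 Ct; oracle comparisons (exhaustive enumeration, KNN,
winsorization, pooled-t closed forms) use matrices small enough to
brute-force exactly. The whole suite runs in about a minute.

## Known limitations

- The min-P machinery assumes complete data; assays with residual
  missing cells are dropped from permutation analysis with a warning
  (they cannot occur after the standard pipeline).
- Pooled-variance permutation p-values are used even in Welch mode's
  nominal tests only when requested; the default keeps both pooled.
- q-value estimation with π₀ = 1 over-counts the null mass when many
  assays are truly differential, making q-values conservative.
- The lowess span and K are exposed but not tuned per dataset; no
  cross-validation is attempted.
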