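# Methods

This note documents the statistical machinery in `copdlc`, the choices made
where the underlying study leaves the method open, and what the synthetic
data can and cannot establish.

## Cohort model

Subjects carry a disease label (control volunteer, COPD case, lung-cancer
case), pre-bronchodilator spirometry, clinical covariates and genotype
calls. Airflow obstruction is graded exactly at the stated thresholds:
GOLD 2+ iff FEV1/FVC < 70 **and** FEV1 ≤ 80% predicted; FEV1/FVC < 70 with
preserved FEV1 is GOLD 1; a ratio of exactly 70 is unobstructed. Analysis
groups follow from label × grade: control volunteers with any obstruction
(GOLD 1+) are excluded (the control phenotype is the "resistant smoker");
COPD cases must satisfy GOLD 2+ (anything else is a phenotype
inconsistency, raised as an error); lung-cancer cases split into
with-COPD / without-COPD sub-phenotypes, and cases lacking usable
spirometry stay in the pooled lung-cancer group only. This last rule is why
the pooled group can be larger than the sum of the sub-phenotypes, matching
the differing column Ns of the source counts.

Cohort tables are TSV with a fixed column set plus one genotype column per
rsID; the missing-genotype sentinel is `NN`, chosen because it cannot
collide with a real genotype. VCF/PLINK ingestion, phasing and imputation
are out of scope.

## Association battery

All inference is on 2×2 tables oriented so that the "exposed" class is the
panel's risk-genotype set (genotype-collapse model) or risk allele (allelic
model), which keeps odds ratios on the tabulated side of 1.

* OR = ad/bc; 95% CI by the Woolf log interval with z = 1.96. This
  reproduces the published intervals to terminal-digit rounding.
* p-values are Pearson chi-square on 1 df without continuity correction.
  The source tables contain (CI, p) pairs that are mutually inconsistent
  (e.g. an interval excluding 1 printed alongside p = 0.06), so p-values
  are reported from this single consistent method and are never treated as
  reproduction targets.
* Zero cells: Haldane's 0.5 is added to all four cells — before the OR, CI
  and chi-square alike — only when a zero cell occurs, and the result is
  flagged. Near-empty cells occur in the rarer genotype classes of two
  panel SNPs.
* Mantel–Haenszel pooling (OR_MH = Σaᵢdᵢ/nᵢ ÷ Σbᵢcᵢ/nᵢ, 1-df MH
  chi-square without continuity correction) is provided; the battery's
  default contrasts are crude, since no stratification variable is
  specified for the published univariate tables.
* No multiple-testing correction: the panel SNPs are selected a priori
  from genome-wide studies.
* Hardy–Weinberg: allele frequency from genotype counts, expected counts
  np², 2npq, nq², Pearson statistic on 1 df.

Six contrasts are computed per SNP: COPD vs control, all lung cancer vs
control, lung cancer with COPD vs control, lung cancer without COPD vs
control, the two sub-phenotypes against each other, and the pooled
"all COPD" group (COPD cases plus lung-cancer-with-COPD) vs control.

### Effect classes (G0–G3)

The published class labels come with no formal rule, so the classifier is
a documented heuristic reconstructed from the printed pattern: a contrast
"hits" when its genotype-model p < α (default 0.05); G0 = protective hit
vs COPD and vs a lung-cancer contrast; else G2 = susceptible hit in a
COPD-containing contrast; else G1 = hit vs COPD only; else G3 = hit in the
no-COPD lung-cancer contrast only; else UNASSIGNED. On the fixture this
reproduces eight of the nine published assignments; the ADAM19 SNP comes
out UNASSIGNED because none of its contrasts reaches 0.05 (its published
G2 call leans on a pooled contrast whose p-value sits exactly at the
threshold). The classifier is deliberately not tuned to force that ninth
label.

## Susceptibility score

score = SNP component + clinical component, computed only for control
smokers and lung-cancer cases.

* SNP component: −1 per protective risk genotype carried, +1 per
  susceptible one; a missing genotype, or any genotype outside the risk
  set, contributes 0. Default 9-SNP panel ⇒ range [−5, +4].
* Clinical component: age > 60 years (+4, strictly greater), family
  history of lung cancer (+3), prior COPD diagnosis (+4); support
  {0, 3, 4, 7, 8, 11}. Missing covariates score 0 for their term.
  Pack-years is a recruitment/matching variable and never enters.
* An OR-weighted variant (weights = signed log ORs from the battery) is
  available behind a flag; the unweighted score is the default, weighting
  having shown no discrimination benefit in the source analyses.

### Quantile binning

Bins (default quintiles) are cut at quantiles of the **pooled**
case + control score distribution — whether the original analysis pooled
or used one arm is unstated; pooled is the deterministic, documented
default. A score equal to a bin edge goes to the lower bin. With fewer
distinct scores than requested bins, duplicate edges are merged with a
warning.

### Floated absolute risk

For bins i = 1..K with case/control counts (aᵢ, bᵢ) and referent r, the
log odds ratio Lᵢ = log(aᵢ/bᵢ) − log(a_r/b_r) has Var(Lᵢ) = vᵢ + v_r and
Cov(Lᵢ, Lⱼ) = v_r, where vᵢ = 1/aᵢ + 1/bᵢ. Floated variances sᵢ² are
fitted by least squares to this covariance structure so that every
between-bin contrast satisfies Var(Lᵢ − Lⱼ) ≈ sᵢ² + sⱼ²; in this
unadjusted polychotomous setting the fit is exact and recovers sᵢ² = vᵢ
for every bin, the referent included — which is what lets the referent
carry its own confidence interval, exp(±1.96·s_r). For K = 2 the
decomposition is taken in closed form (sᵢ² = vᵢ), where the two floated
variances sum exactly to the Woolf variance of the OR. The reconstruction
diagnostic `far_contrast_error` (max relative error of sᵢ² + sⱼ² against
the directly computed pairwise Woolf variances) is reported with FAR
tables; the documented tolerance is 2% relative, though the unadjusted fit
achieves machine precision. Bins with a zero cell receive the Haldane 0.5
and are flagged; a bin empty in both arms is an error.

### ROC / AUC and power

AUC is the Mann–Whitney estimator with mid-ranks, i.e. ties — the norm for
small-integer scores — count half; the curve thresholds every distinct
score. The identity AUC(A,B) + AUC(B,A) = 1 holds exactly and is tested.

Detection power for H₀: AUC = 0.5 uses a two-sided z-test with the exact
Mann–Whitney null variance (m+n+1)/(12mn) and the Hanley–McNeil
exponential-approximation variance under the alternative. Several published
variance approximations exist and commercial power software does not
disclose its choice, so the analytic value (≈ 0.74 at 450 + 450 subjects
for AUC 0.55 at α = 0.05) is validated against a seeded Monte-Carlo
simulation of binormal scores rather than against any published power
figure.

## Synthetic data

### The printed-count fixture

`table_fixture()` is a deterministic 1446-subject cohort whose per-group,
per-SNP genotype counts equal the published table exactly for the control,
COPD and two lung-cancer sub-phenotype columns of all 12 SNPs. Group sizes
are count-driven: 488 controls, 458 COPD, 261 + 207 sub-phenotyped
lung-cancer cases plus 32 with missing spirometry. Per-SNP call-rate
shortfalls become `NN` calls; the whole-cohort lung-cancer column is
recovered by assigning each SNP's count shortfall to the
spirometry-missing subjects. Two arithmetic blemishes of the printed table
are preserved rather than repaired: one sub-phenotype column sums to 261
although its header says 215, and the 4q31 HHIP SNP's whole-cohort column
is smaller, genotype-by-genotype, than the sum of its sub-phenotype
columns — no subject-level cohort can satisfy both, so the sub-phenotype
columns win and the HHIP whole-cohort contrast is the one odds ratio the
fixture does not reproduce.

Genotype columns are filled independently SNP-by-SNP in a fixed rotated
slot order, and clinical covariates are spread at the published marginal
prevalences (largest-remainder rounding) independently of genotype.
Consequences: every count-level quantity (odds ratios, HWE, call rates) is
exact, but joint quantities — score distributions, FAR shape, AUC — are
structural readouts of the marginals, not reproductions of the study's
subject-level results. This is why the published AUC of 0.69 (0.72 with an
extended, unpublished 10-SNP addition) is explicitly not a reproduction
target: it requires the undeposited individual-level joint data.

Clinical marginals used: family history of lung cancer 9/11/19%
(control/COPD/lung cancer); male sex 60/59/53%; age > 60 fractions
0.69/0.75/0.82, derived from the published age summaries (means 65/66/69,
SDs 10/9/10) under normality; prior COPD diagnosis proxied by spirometric
COPD status (0% controls, 100% COPD and lung-cancer-with-COPD, 0%
lung-cancer-without-COPD, 51% among spirometry-missing cases). Ages in the
fixture are coded 70/50 around the >60 boundary; fixture spirometry uses
group-typical values (e.g. 99%/78% for controls, 46%/46% for COPD).

### The generator

`sample_cohort` draws genotypes independently per SNP from each group's
probability triple. Pairs under a concordance constraint (default: the two
4q31 SNPs at 65% genotype agreement, their published linkage
disequilibrium) are drawn from a joint distribution that mixes the
independent coupling with a maximal-agreement coupling; the mixing weight
is solved numerically so the expected agreement hits the target while both
marginals are preserved exactly. Infeasible targets (outside
[Σpq, Σ min(p,q)]) raise. No other between-SNP structure is simulated —
only marginals are published — and no smoking-genotype interaction is
modelled. Spirometry is drawn from clipped group-typical normal
distributions guaranteed to classify into the intended group; pack-years
comes from one common distribution across groups (the design is
smoking-matched). All draws flow from a single `numpy` generator seeded
explicitly; identical spec + seed gives identical cohorts.

`spec_from_battery` inverts a fitted battery into a generator spec by
frequency plug-in, enabling fixture → spec → large-n sample → battery
round trips, which the tests use to check the generator is unbiased for
the odds ratios.

## Problem sizes and numerical choices

The test suite exercises parameter recovery at 10⁵ subjects per group over
three fixed seeds (the generator is vectorised; the whole suite runs in
well under a minute) and validates the 2×2 machinery exhaustively over all
2 400 tables with cells ≤ 6 against first-principles recomputation.
Statistical sampling checks use 3-standard-error per-quantity tolerances
with a family-wise exceedance allowance at the level sampling theory
predicts, plus a 4.5-SE gross-error bound. Monte-Carlo power companions
use 800–2000 replicates. Floats are compared at machine-precision relative
tolerances wherever the algebra is exact (FAR closed form, AUC
complement, OR reciprocity).

## Limitations

* The fixture's joint structure is synthetic; conclusions about score
  discrimination on real data cannot be drawn from it.
* The G0–G3 classifier is a reconstruction; borderline loci (p ≈ α) may
  legitimately differ from published labels.
* The allelic model assumes biallelic SNPs and independence of alleles
  within genotype (no inbreeding adjustment).
* Histology sub-analyses, population-stratification runs and the extended
  19-SNP score are out of scope (data unpublished).
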