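# Methods

`nigra` implements the quantitative workflow for studying male-infant
affiliation in wild crested macaques (*Macaca nigra*): whether adult
males and dependent infants interact at random or form preferential
bonds, and which social factors — dominance rank, paternity, the
mother's presence, the mother-male bond — predict who initiates daily
affiliations.  Because studies of this kind rest on non-deposited field
and lab data, the package pairs every analysis stage with a synthetic
generator that emulates the data-generating process, so each stage can
be validated by parameter recovery rather than by re-fitting the
original observations.

## Synthetic data generator (`nigra.synth`)

The generator emulates a two-year field study of three social groups
(defaults: 18 resident adult females and 8 adult males per group over
730 days), driven by a single seed.

**Demography.** Females are philopatric and present throughout.  Males
immigrate and emigrate; tenures are Gamma-distributed with mean 766.5 d
and SD 396.7 d (a Gamma rather than an exponential because the target
SD is about half the mean), and a departing male is immediately
replaced so group composition stays within the configured bounds.
Births arrive per female at `birth_rate` (default 8 x 10^-4 per
female-day, giving roughly 30 infants at default scale) with a 365-day
refractory period.

**Paternity.** Each conception window spans 14 days ending 165 days
before birth (both configurable; gestation placement is a design
choice, not an inference).  The sire is drawn from the males resident
during the window with probability proportional to their min-max
standardized latent strength raised to `paternity_skew` (default 8,
emulating strong alpha monopolization; `skew = 0` is uniform,
`skew -> inf` deterministic).

**Agonism.** Each adult carries a standard-normal latent strength.
Decided agonistic events are Poisson-thinned per group, sex and day;
the stronger contestant wins with logistic probability in the strength
difference, scale 0.5 (≈0.88 win probability per 1 SD gap).  The steep
scale reflects the strongly unidirectional agonism of macaque dominance
hierarchies and makes the latent hierarchy identifiable by a sequential
rating scheme.

**Focal follows.** Each infant is followed daily from birth to one
year: a Poisson number of 1-min scans per day (mean 30), per-scan
presence of the mother within 2.5 m (declining with infant age, ~50%
at five months), independent per-scan proximity of each co-resident
male, and a latent mother-male bond propensity governing affiliation
in co-presence scans.  The daily log-odds that a dyad's affiliation is
initiated in each direction follow the configured `true_effects` linear
predictor (z-scored covariates; defaults: mother presence -0.2, male
rank +0.15, mother-male bond +0.1 on the logit scale), an
observation-effort offset `ln(scans/30)`, and a stationary per-dyad
AR(1) latent term (`ar1_rho` 0.9, `ar1_sd` 1.0) that gives the
autocorrelation machinery genuine signal.  Event multiplicities are
tuned so the infant-initiated share of affiliations matches its
configured value (default 63.5%).

**Genotypes.** Twelve microsatellite loci with six alleles each; allele
frequencies are Dirichlet(1, ..., 1) draws per locus.  Founders are
Hardy-Weinberg draws; offspring inherit Mendelian alleles.  Each
replicate PCR of a heterozygote drops each allele independently with
`dropout_rate` (a replicate losing both re-amplifies one at random, so
the single-allele fraction is `1 - (1 - d)^2`), and every amplified
copy is replaced by a random allele with `misprint_rate`.

**What the generator does not emulate:** infant mortality and
censoring, observer effort gaps, linkage between loci, relatedness
among candidate males, within-day temporal structure, and spatial
behavior.  Passing recovery tests therefore show that the pipeline's
estimators are consistent under the assumed data-generating process,
not that the original field estimates are reproduced.

## Elo ratings (`nigra.elo`)

Sequential Elo with start 1000, k = 100, base-10 logistic expectation
with scale 400 — the conventional defaults of the animal-dominance Elo
literature; all three are configurable.  Updates are zero-sum.  New
residents enter at the start rating.  Raw scores are min-max
standardized to [0, 1] per (group, sex, day); degenerate strata (one
individual, or all tied) map to 0.5, the midpoint avoiding fabricated
extreme ranks.

## Consensus genotyping (`nigra.genotyping`)

Multi-tube rules: heterozygote accepted when both alleles are confirmed
at least twice across at least four replicates; homozygote when one
allele appears in at least six replicates and no second allele was ever
confirmed twice; conflicting patterns go to extension (up to 11
replicates) and the same two rules are re-applied in priority order,
with the homozygote call additionally requiring that the minority
allele was seen only once.  Three alleles confirmed twice is treated as
contamination.  Locus statistics: gene-count allele frequencies,
observed heterozygosity, PIC, a seeded Monte-Carlo exact Hardy-Weinberg
test (allele copies shuffled and re-paired; chosen over the asymptotic
chi-square because microsatellite genotype classes are sparse), the
null-allele index `(He - Ho)/(He + Ho)` with `He = 1 - sum p_i^2`
(no small-sample correction), and

    PID    = 2 (sum p_i^2)^2 - sum p_i^4
    PIDsib = 1/4 + 1/2 sum p_i^2 + 1/2 (sum p_i^2)^2 - 1/4 sum p_i^4

with multi-locus values as products and the minimum locus count for
identity taken over the most informative loci first.

## Parentage (`nigra.parentage`)

Maternity is verified first (shared allele at every jointly called
locus, at least eight loci).  Paternal exclusion asks, per locus,
whether any Mendelian (maternal, paternal) split of the offspring pair
is compatible with the candidate; loci with missing genotypes are
skipped and not counted as compared.  Assignment categories in
precedence order: strict (sole zero-mismatch candidate, others >= 2),
standard (others >= 1), relaxed (no zero-mismatch candidate, exactly
one with a single mismatch, others >= 2), conception-presence tiebreak
among multiple zero-mismatch candidates, else unresolved.

The LOD score is the natural-log ratio of the offspring-genotype
probability given the candidate as sire versus a sire drawn from the
allele frequencies, under a single per-genotype error rate (default
0.01): each observed genotype is treated as correct with probability
`1 - e` and as a Hardy-Weinberg draw otherwise.  The simulation-based
confidence simulates offspring under "candidate is the sire" and
"random sire" scenarios and reports, among simulations whose
best-vs-second-best LOD gap meets the observed gap, the share that are
correct true-sire assignments — a posterior-style confidence that is
~0 for uninformative panels and >= 0.95 for a 12-locus panel.

## Permutation test (`nigra.permtest`)

Events are cross-tabulated per group and direction, keeping only adult
males present for the entire study period.  The initiator column of the
event list is shuffled (event-level shuffling preserves both initiator
and recipient totals, so the expected counts are permutation-invariant),
the Pearson chi-square recomputed, and the observed data counted as one
of the 10,000 permutations; the upper-tail count is the two-sided test
because chi-square is non-directional.  All-zero rows/columns are
dropped before the statistic.  Preferred partners are flagged by the
adjusted standardized residual `(O - E) / sqrt(E (1 - p_row)(1 -
p_col)) > 1.96`; this criterion is a documented stand-in — field
reports quote preferred-partner counts without defining the rule.

## Model table (`nigra.modeltable`)

One row per (male, infant, focal day) with both dyad members resident;
the response is whether at least one qualifying affiliative event
(tolerated approach, grooming, friendly behavior) was initiated that
day in the model's direction.  Mother presence is the daily count of
scans with the mother within 2.5 m, transformed `log(x + 1)` (zeros
occur) and z-scored; the mother-male affiliation is by default the
*running* (study-start-to-date) proportion of their co-presence scans
with an affiliation — the cumulative window is defined for every row
and stabilizes as data accrue; a daily window is available behind a
switch.  Seasonality enters as `sin/cos(2 pi doy / 365.25)`.  All
continuous predictors are z-scored table-wide; the offset is
`ln(scans that day)`.  Infants without an assigned sire are excluded,
and an infant's rows end when its sire leaves the group.  Constant
predictors either raise or are dropped, per configuration.

## AC-GLMM (`nigra.acglmm`)

Binomial-logit mixed model with independent (diagonal-covariance)
Gaussian random effects: intercepts for male, infant, dyad, group and
day, plus a configurable random-slope subset (`glm`, `none`, `reduced`,
`full`).  The reduced subset is the default for desk-scale data; the
full 15-slope structure rarely has information to converge at small n.

The marginal likelihood uses the Laplace approximation: for each
candidate vector of log random-effect SDs, the joint mode of (fixed
effects, random effects) is found by penalized IRLS with backtracking,
and the approximate log marginal likelihood is the penalized
log-likelihood at the mode minus `0.5 log det(I + D^{1/2} Z'WZ
D^{1/2})`.  The outer optimization is Nelder-Mead from a fixed start
(log sigma = log 0.5), making fits deterministic; warm starts are
reused across the bandwidth search and pruning.  With no random terms
the fit is an exact logistic regression (verified against statsmodels
to 1e-6; the mixed fit is verified against lme4's Laplace glmer).
Fixed-effect SEs come from the fixed block of the inverse penalized
Hessian (conditional SEs, as is standard for Laplace fits).

**Autocorrelation terms.**  For each row, the AC covariate is the
Gaussian-kernel weighted mean of the *response-scale* residuals
(`y - fitted p`; working residuals are available) of all other rows
sharing the key (one term keyed on the infant, one on the male),
weights `exp(-dt^2 / 2 sigma^2)` in days, excluding the row itself;
rows with no partner get 0.  Each kernel SD is chosen to maximize the
refitted model's log-likelihood over a log-spaced grid (1-256 days)
refined by bounded golden-section search; the two keys are optimized
sequentially (infant, then male conditional on the infant term) — a
joint scheme is possible but the sequential one matches the
two-separate-terms construction and is cheaper.  A flat profile
(optimum at the grid's upper bound) is flagged as "no detectable
autocorrelation".

**Inference.**  The full-vs-null LRT compares the full fixed structure
against the model retaining only AC terms, offset, controls and random
terms; degrees of freedom are parameter-count differences.  The
canonical full structure has 13 test terms in the infant model (five
mains: paternity, male rank, mother rank, mother presence, mother-male
affiliation; six two-way and two three-way interactions) and 14 in the
male model (adding presence at conception).  The six two-ways comprise
the five pairs nested in the two rank x paternity x (presence | bond)
three-ways plus mother presence x mother-male affiliation; including
the presence x bond pair makes the infant/male test-term counts 13/14
— the single structure consistent with both models' full-vs-null
degrees of freedom — and is substantively motivated (the bond can only
express itself when the mother is near).  Interaction pruning is
hierarchical backward LRT at alpha = 0.05: three-ways first, then
two-ways, in declaration order, with two-ways protected while a
retained three-way contains them.  VIF uses main effects only
(`1/(1 - R^2)` from OLS of each predictor on the rest); the stability
check refits the final model leaving out each level of each grouping
factor and reports the largest fixed-effect shift.

## Problem sizes of the validation studies

The canned studies (`nigra.studies`) choose desk scales as the
package's own defaults: permutation type-I calibration over 500 null
datasets of 60 events at 400 permutations; exact-enumeration agreement
on 7-event lists; sire recovery on 30 offspring x 20 candidates x 12
loci at dropout 0.05; mismatch-oracle agreement on 1,000 random trios;
AC-gain rate over 50 single-group studies (8 females, 5 males, 140
days); sign recovery over 100 single-group studies (14 females, 8
males, 240 days, ~13,000 dyad-days each), fit as logistic regressions —
at these effect sizes the planted signs are recovered with mean
|z| between 2.5 and 6, and the mixed-model machinery is validated
separately against lme4.

## Known limitations

- Random effects are independent (no slope-intercept correlations),
  unlike lme4's default unstructured blocks.
- The AC bandwidths are optimized on base-model residuals held fixed;
  the original two-step scheme is emulated, not re-derived.
- The simulation-based paternity confidence is a simplified stand-in
  for a full CERVUS-style simulation (no candidate relatedness or
  sampling-fraction modeling).
- Group sizes in the generator are kept constant by immediate male
  replacement; demographic drift is out of scope.
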