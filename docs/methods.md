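# Methods

This note documents the models, rules and design choices behind
`nafldpheno`, in the order the pipeline runs them.

## Time model

All timestamps are integer days relative to enrollment (day 0); "prior to
enrollment" means day ≤ 0, and a lab drawn on the enrollment day itself
counts as pre-enrollment. "Six months" is fixed at 183 days and the
"two-year window" at 730 days; calendar-month arithmetic is deliberately
avoided so results are deterministic and independent of enrollment dates.

## Phenotype rules

The qualifying-pair rule asks for two ALT values strictly above the
sex-specific case threshold whose days differ by at least 183 and at most
730 — the window constrains the *gap between the pair*, not their distance
from enrollment. Controls must have at least one pre-enrollment ALT and
every value at or below the control ceiling; this "max-based" reading is
what makes the intermediate ALT band (30–40 U/L men, 20–30 women) a
well-defined stratum that is dropped from the analytic cohort. Participants
with elevated ALT but no qualifying pair are likewise indeterminate rather
than cases or controls: indeterminacy preserves case specificity at the
cost of sample size. Under metabolic-mode definitions, a participant with a
qualifying pair but without the required factor(s) is also indeterminate —
dropped from that definition's analytic cohort, not demoted to control —
which reproduces the arithmetic by which the metabolic phenotype's cohort
is smaller than the primary one by exactly the factor-negative cases.

ICD matching is case-insensitive prefix matching on dot-stripped codes
("272.x" ⇒ prefix `272`), with optional exception prefixes (used for the
prediabetes list, where two sub-codes are excluded). The exclusionary and
risk-factor code lists ship as editable config data (`config.py`, or a YAML
overlay via `load_config`): the study-specific supplementary lists are not
public, so the defaults cover the named categories and are meant to be
replaced per site.

Metabolic risk factors use the most recent pre-enrollment observation per
analyte throughout. Decisions a user should know about:

* a triglyceride draw with no time-of-day stamp can never satisfy the
  "≥150 mg/dL before 9 AM" criterion (conservative);
* "at least two prescriptions" means records on ≥ 2 distinct days;
* the type-1-diabetes pattern (insulin without oral agents, onset age < 40,
  BMI < 25, or ketoacidosis history) blocks only the diagnosis-code route
  to the T2D flag — the lab and prescription routes are evaluated as
  written; onset age is the age at the earliest diabetes code or
  qualifying lab;
* hypertension is derived (codes 401.x–405.x / I10–I16) and used as a
  Model-3 covariate, but does not count toward the "any metabolic factor"
  requirement, which lists obesity, dyslipidemia, T2D and prediabetes only;
* the AUDIT-C covariate is the raw most-recent score; the alcohol-misuse
  flag uses the standard VA cutoffs (≥4 men, ≥3 women).

Reported percentages round half-up at the printed precision.

## Fibrosis scores

FIB-4 and NFS are evaluated exactly as printed, with platelets in 10⁹/L
internally (inputs in cells/µl should be divided by 10³ at the reader). The
NFS dysglycemia term is diabetes OR prediabetes — this cohort's variant of
the original score — applied as written. The advanced-fibrosis boundary for
NFS is inclusive (≥ 0.676, the convention of the results tables) by
default and switchable to strict (the methods-text reading); FIB-4 uses
strict > 2.670 and the low-platelet flag strict < 150.

## Association and meta-analysis

Per-stratum fits are plain maximum-likelihood logistic (binary) or OLS
(continuous) regressions via statsmodels, with Wald standard errors and
two-sided normal p-values — the standard GWAS/METAL convention; no Firth or
rare-variant correction is applied. Dosages are accepted as continuous in
[0, 2] (imputation-ready) although the generator emits integers. Degenerate
designs — constant dosage, a single outcome class, separation, singular or
unstable fits (se > 10³) — are flagged non-estimable rather than raised,
and are dropped from the meta-analysis. The fixed-effects combination and
Cochran's Q are computed from first principles (closed forms, tested to
1e−12); an independent Newton–Raphson implementation serves as the oracle
for the regression route in the test suite.

## Synthetic cohort generator

The generator emulates the study conditions the phenotype was developed
under, so its defaults are fixed rather than tunable knobs: ancestry mix
72.8 / 20.2 / 7.0% EU/AA/LA, 8.4% female, age 64.5 ± 13.1 years, case
prevalence 0.31 in the analytic cohort, and status-conditional metabolic
factor rates matching the published case/control marginals (obesity
57.3/40.8%, hypertension 81.6/66.2%, T2D 35/21.8%, prediabetes 33.4/39.6%,
dyslipidemia 67.7/43.0%). The 16-variant panel carries the European effect
allele frequencies for all ancestries (per-ancestry frequencies were not
published; they are overridable per variant), and planted per-allele
log-odds effects equal to the published Model-1 odds ratios for the eight
NAFLD-risk variants and zero for the eight ALT-level-only variants, since
effects are planted on case status alone.

Genotypes are Hardy-Weinberg draws (Binomial(2, EAF)); no linkage
disequilibrium between variants and no dosage uncertainty are simulated.
Case status is logistic in the planted effects with the intercept solved by
root-finding so the realised marginal prevalence equals its target;
covariate effects on case status default to zero so recovery tests stay
interpretable. Lab series are inverse-designed against the rules: planted
cases receive a qualifying ALT pair (gap uniform on [183, 600] days) plus
sub-threshold noise draws, planted controls stay at or below the ceiling,
and a configurable fraction (default 15%) has maximum ALT inside the
intermediate band; 5% receive an exclusionary liver-disease code. ALT
trajectories are i.i.d. noise around a status-dependent level — adequate
for rule testing, not for longitudinal trajectory modelling. Metabolic
flags are expressed through randomly chosen evidence routes (e.g.
dyslipidemia via morning triglycerides, low HDL + two codes, or a fibrate);
planted T2D always includes two diabetes-medication days so the flag
survives the type-1-pattern exclusion regardless of the drawn BMI. AUDIT-C
scores are Binomial(12, p) with p = 0.25 (men) / 0.18 (women), putting
roughly a third of the cohort over the misuse cutoffs.

Chart adjudication is simulated as independent raters with set sensitivity
and specificity against truth (pipeline default 0.95/0.95 on a 457-record
case-enriched sample).

All randomness descends from one integer seed through spawned NumPy
`SeedSequence` streams, so each emitted table is reproducible independently
of the others and whole runs are bit-identical given the config.

**What passing tests do and do not show.** Because labs are
inverse-designed, perfect round-trip recovery demonstrates that the rule
engine implements the stated rules, not that the rules are accurate in real
EHR data; the generator contains no miscoded units, no missing sex, no
transfers between systems, and its evidence routes are exactly the ones the
rules look for. The planted-effect recovery and coverage results likewise
validate the estimation machinery, not the published effect sizes, which
require the original cohort.

## Problem sizes and numerical choices

Simulation-based checks use 1,000 null replicates at n = 2,000 for type-I
error, 50 replicates at n = 50,000 for CI coverage of a planted OR of 1.31
at EAF 0.23, and cohorts of a few thousand for round-trip and pipeline
tests — sizes at which the binomial error bands quoted in the tests are
meaningful. Intercept root-finding brackets the solution analytically from
the logit of the target prevalence and the range of the genetic score.
Kappa with both raters concentrated on the same category is defined as 1;
p-values are never truncated; meta-analysis requires at least one estimable
stratum and refuses mixed-variant input.

## Known limitations

No NLP over clinical notes, no ICD-9→10 mapping service, no calendar or
timezone handling, no LD structure, no random-effects meta-analysis, no
regional association plotting, and no sensitivity/specificity/NPV claims
(the chart-review sampling design supports PPV only). The supplementary
sensitivity phenotypes are implemented as parameterisations of
`PhenotypeDefinition` and remain configurable rather than canonical, since
their exact published definitions are not in the public text.
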