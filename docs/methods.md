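# Methods notes

## Model and procedure

The pipeline treats a bulk tumor/normal study as four chained estimation
problems on one log2-scale expression matrix *X* (features × samples):

**Differential expression.** Each feature gets a two-sided Welch
(unequal-variance) t-test between tumor and normal samples. Welch rather
than Student is used because tumor cohorts are typically much larger than
their adjacent-normal arms and per-group variances differ; with a 369-vs-50
design the pooled test's size can drift. Class-specific raw-p thresholds
call tumor-specific features: 0.05 for ICPR genes, 0.01 for lncRNAs. No
multiple-testing correction gates the calls — the stricter lncRNA threshold
is the procedure's only guard — but Benjamini–Hochberg adjusted p-values
are computed and written alongside so a user can re-gate on them. The test
is feature-level: a gene shared by several populations carries one
statistic. Degenerate input (zero variance in both groups) is defined, not
an error: equal means give (t, p) = (0, 1), unequal means (±∞, 0).
Direction ties (exactly equal means) are labeled "down"; such features are
never significant, so the tie-break only serves determinism.

**Differential co-expression.** Within each population, Pearson
correlations of every tumor-specific gene against every tumor-specific
lncRNA are computed separately per sample group (p-values from the
t-distribution with n − 2 df, recorded but not filtered on by default).
The screening statistic is Δ = |r_tumor − r_normal|, compared strictly
(">") at two thresholds: 0.3 for the screened pair list and 0.7 for network
edges, both configurable (a single intermediate 0.5 cut is reachable via
config). Change patterns: r_N < 0 ≤ r_T is negative→positive, r_N > 0 ≥ r_T
positive→negative, otherwise same-sign strengthened/weakened by comparing
|r_T| with |r_N| (equal magnitudes count as weakened). The Δ histogram is
pooled over populations with recurring gene–lncRNA pairs counted once per
population, since a pair genuinely recurs in several networks. The
integrated network collapses a recurring edge to its maximum-Δ instance — a
simple graph cannot hold parallel edges, and the strongest signal is the
one of interest. The scale-free check is an ordinary least-squares fit of
log10(frequency) on log10(degree) over degrees ≥ 1 with nonzero frequency;
at least three distinct degrees are required for the fit to mean anything.

**Immune-risk scoring.** Only tumor patients are scored, because the groups
are defined for patients. For each network feature, patients are ranked by
expression descending; ties are broken by patient id so the call is
reproducible. The top block holds ceil(0.3·N) patients (a rounding guard
keeps ceil exact when 0.3·N is an integer in rational arithmetic). The
"last 70%"/"top 30%" fractions are complements, so this single boundary
index governs both rules: up-regulated features are risk features for
patients outside the top block, down-regulated ones for patients inside it.
The 50% population rule is strict: a patient must hold strictly more than
half of a population network's nodes (genes and lncRNAs alike — the rule is
stated over network contents) as risk features. Populations with empty
networks are dropped from scoring and from the population total. Group
bounds default to counts ≤ 4 (min-immune), ≤ 9 (media-immune), else
multi-immune; the two-group sensitivity splits put count ≥ boundary in the
high group.

**Survival.** Kaplan–Meier estimation and the unweighted k-sample log-rank
test are delegated to lifelines; curves are reported at observed event
times with deaths preceding censorings at ties (the standard convention).
Patients without clinical records are dropped with a logged count. The
endpoint is whatever the clinical table encodes; nothing assumes overall
vs disease-specific survival.

## Preprocessing choices

The zero filter defaults to removing any feature containing a zero — the
strictest reading of "features with zero values are removed" and the one
that makes log2 safe with no pseudocount at all. `zero_filter_frac` relaxes
it to a tolerated zero fraction, in which case the default pseudocount of 1
(log2(x+1), the standard for level-2-style quantifications) guards the
transform. Whether a real study intended "any zero" or "all zeros" is not
derivable from the procedure itself; both are supported and the default is
documented here.

## Synthetic data: what it emulates and what it does not

The generator writes features i.i.d. normal on the log2 scale
(mean 6, sd `noise_sd`) — the pipeline's statistics (t, Pearson, ranks) all
operate on that scale, so count-level marginals (negative binomial, library
size, batch) are deliberately out of scope. Defaults are chosen as a
realistic desk-scale cohort: 369 tumors vs 50 normals (the classic
tumor-heavy imbalance), 17 populations × 24 marker genes, 400 lncRNAs,
half the background features differentially expressed at 1.5 log2 units
(marker catalogs in tumors show large DE fractions), 8 planted
co-expression pairs per population at |r| = 0.9 flipping sign between
groups, exponential survival with a per-risk-population hazard ratio of 0.8
(more risk populations → better prognosis, matching the motivating
observation; set it > 1 to reverse the sign — detection is two-sided) and
40% independent censoring.

Planted pairs are assigned to genes hub-skewed (pair *j* of a population
goes to gene ⌊log2(j+1)⌋), so networks have degree diversity the way real
co-expression networks do, and each pair's lncRNA is drawn conditionally on
its gene's values (correlation exactly r in population). Two lncRNAs
sharing a hub gene are therefore mutually correlated by r² in *both*
groups — a non-differential correlation the screening correctly ignores.
Planted-pair features are always differentially expressed with alternating
directions (a network mixing up- and down-regulated features keeps the
per-patient risk probability away from 0 and 1, so cohorts spread over all
three groups); `frac_de` applies to the remaining background features.

The ground-truth risk count per patient applies the rank-based scoring to
the planted networks and planted directions — it is the count the pipeline
would produce under perfect feature recovery, and it is what the survival
simulator's hazard depends on. Passing end-to-end tests therefore shows the
pipeline recovers planted structure and detects a real group–survival
association; it does not show anything about marginal realism, batch
effects or tumor purity, which are non-goals.

## Numerical and degenerate-input conventions

- Correlations are computed vectorized from standardized residual products
  and clipped into [−1, 1]; features constant within a sample group are
  excluded from correlation with a warning (scalar `pcc` raises instead).
- All Δ and majority thresholds compare strictly (">"); fraction × count
  products are rounded at 1e-9 before ceil/compare so exact boundaries
  (e.g. 0.3 × 20) behave as in rational arithmetic.
- Empty networks are valid outputs (warning, not error); scoring and the
  power-law fit skip them.
- Every stage is a pure function of its inputs; the only randomness in the
  package is the generator's seeded `numpy` Generator, so fixed seed ⇒
  byte-identical outputs.

## Problem sizes in the test suite

Oracle-equivalence and calibration tests run at small n (≤ 10 patients for
exact brute-force comparison; 1000 features × 10 seeds for t-test
calibration; 1000 replicates for log-rank size, 200 for power; 20 seeds of
a 300-tumor/50-normal cohort for the end-to-end checks) — sizes at which
the binomial error bands quoted in the tests are meaningful while the whole
suite stays interactive.

## Known limitations

- The bundled 17-population GMT is a synthetic stand-in with representative
  marker symbols, intended for smoke tests and examples; real analyses
  should supply a curated catalog.
- lncRNA direction comes from the single cohort-wide test, not per-network
  re-testing; the alternative is not expressible without a per-population
  lncRNA membership, which the data model does not have.
- No covariate adjustment (Cox), no paired designs, no batch correction;
  p-value–gated screening inherits the usual caveats of raw thresholds.
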