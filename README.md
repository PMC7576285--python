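# immrisk

Identification of immune-related lncRNAs in tumor expression profiles and
rank-based stratification of patients into immune-risk groups, for
bioinformaticians analysing bulk tumor/normal cohorts (the design target is
liver hepatocellular carcinoma with marker genes for 17 immune cell
populations, but nothing is tissue-specific).

## The method

Given a log2-scale expression matrix of coding genes and lncRNAs over tumor
and adjacent-normal samples, a catalog of immune-cell-population-related
(ICPR) marker gene sets, and clinical follow-up:

1. **Differential expression.** Every ICPR gene and every lncRNA gets a
   two-sided Welch t-test between tumor and normal. Genes are called
   tumor-specific at *P* < .05, lncRNAs at *P* < .01; direction is up when
   the tumor mean exceeds the normal mean.
2. **Differential co-expression.** Per population, Pearson correlations
   r<sub>T</sub> and r<sub>N</sub> of each tumor-specific gene–lncRNA pair
   are computed separately in tumor and normal samples. Pairs with
   ΔPCC = |r<sub>T</sub> − r<sub>N</sub>| > 0.3 are screened in and
   classified by change pattern (negative→positive, positive→negative, or
   same-sign strengthened/weakened); pairs with ΔPCC > 0.7 become edges of
   bipartite per-population networks and an integrated network, whose
   degree distribution is checked for scale-freeness by an OLS fit of
   log₁₀ *f*(*d*) on log₁₀ *d*.
3. **Immune-risk scoring.** For each network feature, tumor patients are
   ranked by expression from high to low. Patients ranked in the last 70%
   carry an up-regulated feature as a *risk feature*; patients ranked in
   the top 30% carry a down-regulated one. A population is a *risk
   population* for a patient when more than 50% of its network features are
   risk features. Patients are stratified by risk-population count into
   min-immune (0–4), media-immune (5–9) and multi-immune (10–17) groups.
4. **Survival.** Kaplan–Meier curves per group and the unweighted k-sample
   log-rank test (plus two-group splits at count boundaries 6 and 7).

A synthetic-data generator (`immrisk.synthetic_data`) produces cohorts with
planted differential expression, planted differential co-expression pairs,
and survival times whose hazard is multiplicative in the true per-patient
risk-population count, so every stage can be validated against ground truth.

## Worked example

```python
from immrisk.synthetic_data import SimConfig, simulate_expression, simulate_survival
from immrisk.pipeline import run_study

sim = SimConfig(n_tumor=120, n_normal=40, n_populations=17,
                genes_per_population=12, n_lncs=150, seed=7)
x, sets, truth = simulate_expression(sim)
clinical = simulate_survival(truth.risk_counts, sim)

res = run_study(x, sets, clinical)
print(f"screened pairs (|dPCC| > 0.3): {len(res.pairs)}")
print(f"integrated network edges (|dPCC| > 0.7): {len(res.networks['integrated'])}")
print(f"degree distribution: slope {res.power_law.slope:.2f}, R^2 {res.power_law.r_squared:.2f}")
print(f"immune-risk groups: {res.group_sizes}")
print(f"three-group log-rank: chi2 {res.log_rank.statistic:.2f}, p {res.log_rank.p_value:.4g}")
```

prints

```
screened pairs (|dPCC| > 0.3): 2189
integrated network edges (|dPCC| > 0.7): 137
degree distribution: slope -1.66, R^2 0.77
immune-risk groups: {'min_immune': 20, 'media_immune': 95, 'multi_immune': 5}
three-group log-rank: chi2 8.97, p 0.01125
```

2189 gene–lncRNA pairs changed correlation by more than 0.3 between tumor
and normal; 137 strong changes (> 0.7) form the integrated network, whose
degree frequencies fall roughly as a power law. Scoring the 120 tumor
patients spreads them over the three immune-risk groups, and the groups'
survival differs (log-rank p ≈ 0.01 — here driven by the generator's planted
hazard, which decreases with the risk-population count).

The same analysis runs from the shell: `immrisk simulate --out study/`
writes a synthetic study, `immrisk run --config run.yaml` executes the whole
pipeline, and `immrisk de / coexpr / network / score / survive` run single
stages over the TSV intermediates.

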