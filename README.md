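# mcdaval

Multicriteria decision analysis (MCDA) for drug value assessment.

Hospital formulary committees and health-technology-assessment groups
increasingly have to justify adding an expensive drug by more than a single
cost-effectiveness ratio.  `mcdaval` implements the full weighted-sum MCDA
workflow such panels use, end to end:

1. **Criterion weighting (AHP).**  A two-level criteria hierarchy (domains →
   criteria) is weighted from expert pairwise comparisons on the Saaty 1–9
   scale.  Priorities are the principal right eigenvector of each judgment
   matrix; group judgments are combined by element-wise geometric mean
   (optionally weighted by each expert's authority coefficient
   Cr = (Ca + Cs)/2).  Saaty consistency diagnostics (λ_max, CI, RI, CR)
   guard against incoherent judgments.
2. **Evidence scoring.**  Experts score each criterion for each strategy on
   a 1–10 scale against an evidence matrix.  Per criterion, the comprehensive
   score is CS = W_c × ES_c (global weight × mean expert score); a strategy's
   overall value is ∑ over all criteria of W_c × ES_c.
3. **Sensitivity analysis.**  Overall values are recomputed under alternative
   domain-weight scenarios and rankings compared against baseline to assess
   rank stability.
4. **Pharmacovigilance signals.**  Spontaneous adverse-event reports are
   screened by disproportionality: PRR = (a/(a+b))/(c/(c+d)) with Pearson χ²
   (Yates-corrected), and ROR = ad/bc with a Woolf 95 % CI.  A drug–event
   pair is a signal only under the dual rule
   (PRR > 2 ∧ χ² ≥ 4) ∧ (N ≥ 3 ∧ CI lower bound > 1).
5. **Affordability and access.**  Annual course cost from a dosing regimen,
   daily cost, cost as a share of annual household disposable income, and
   formulary coverage rates across surveyed institutions.

A synthetic-data module generates every input the pipeline consumes — noisy
expert judgment matrices around a true weight vector, integer score panels
with specified means/dispersions, and spontaneous-report tables with
implanted signals — so the whole chain is testable with controlled ground
truth.

## Worked example

The package bundles the inputs of a published case study: omalizumab (an
anti-IgE antibody) plus standard of care (SOC) versus SOC alone for
moderate-to-severe pediatric allergic asthma, with six domains, 15 criteria
and a 17-expert panel.

```python
import mcdaval as m

cs = m.omalizumab_case_study()
fit = m.MCDAModel.from_summaries(cs.hierarchy, cs.esc_means, cs.esc_sds).fit()
print(fit.summary())
```

prints (abridged):

```
Weighted-sum MCDA value model
6 domains, 15 criteria, strategies: OMZ+SOC, SOC

       domain                              criterion ESc OMZ+SOC CS OMZ+SOC     ESc SOC CS SOC
       safety                   A1 Pre-market safety 7.71 ± 1.02       1.53 7.24 ± 1.96   1.43
effectiveness                   B2 Clinical efficacy 8.76 ± 0.64       1.18 6.71 ± 1.67   0.91
...
       safety                                  Total           -       2.81           -   2.83
effectiveness                                  Total           -       2.34           -   1.94
...
      Overall                                                  -       7.39           -   7.19

ranking: 1. OMZ+SOC (7.39); 2. SOC (7.19)
```

Each `CS` cell is the criterion's weight times its mean expert score (e.g.
0.1982 × 7.71 → 1.53 for pre-market safety); domain `Total` rows sum the
criteria, and `Overall` sums the domains — the add-on strategy scores 7.39
points versus 7.19 for standard of care alone.  Sensitivity follows
directly:

```python
stab = fit.sensitivity(cs.scenarios)   # six published weight scenarios
print(stab.stable)                      # True: OMZ+SOC ranks first in all six
```

The same operations are available from the shell via the `mcdaval` CLI
(`weights`, `score`, `sensitivity`, `signal`, `afford`, `simulate`,
`validate`, `run`), composing through CSV/YAML intermediates; `mcdaval run
--config run.yaml` executes the whole pipeline and writes per-table CSVs, a
JSON bundle and a run manifest.

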