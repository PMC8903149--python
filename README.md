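# ipvalign

Cross-group measurement-invariance analysis for dichotomous survey items,
built for the setting in which many country surveys administer the same
binary item set — for example the domestic-violence module questions on
lifetime physical intimate-partner violence (7 items) or male controlling
behaviour (5 items) — and analysts want to know whether national scores on
the latent construct can be compared at all.

The package is aimed at psychometricians and survey methodologists. It
implements the full measurement-invariance workflow as a tested, reusable
library plus CLI, and ships a synthetic multi-group generator with known
ground truth so every stage can be validated end to end without access to
restricted survey microdata.

## The model and the workflow

Responses follow a unidimensional two-parameter probit item-response model.
For respondent *i* in group *g* with latent trait
η ∼ N(α_g, ψ_g):

```
P(y_ij = 1 | η) = Φ(λ_jg · η − τ_jg)
```

with loadings λ_jg and thresholds τ_jg. The four analytic steps:

1. **Descriptives** — per-item missingness and survey-weighted prevalence,
   plus the "any item" composite prevalence per group.
2. **Group-specific factor analysis** — probit thresholds, pairwise
   tetrachoric correlations (two-stage ML with pairwise deletion), a
   one-factor ULS fit with a mean-scaled χ², and the adequacy gate:
   all standardized loadings ≥ 0.35, RMSEA ≤ 0.08, CFI ≥ 0.95, TLI ≥ 0.95.
3. **Exact invariance** — multiple-group marginal maximum likelihood
   (Gauss–Hermite quadrature) under configural, metric (shared λ) and scalar
   (shared λ and τ) constraints, compared by likelihood-ratio tests.
4. **Approximate invariance by alignment optimization** — starting from the
   configural solution, estimate group factor means and variances minimizing
   the total simplicity loss
   `F = Σ_j Σ_{g1<g2} √(n_g1 n_g2) [f(λ_jg1 − λ_jg2) + f(τ_jg1 − τ_jg2)]`
   with component loss `f(x) = (x² + ε)^¼` (ε = 0.01). Parameters outside
   the largest statistically compatible group set are flagged non-invariant;
   at most 25% flagged parameters indicates a trustworthy solution, and a
   Monte-Carlo check (regenerate → refit → realign) should show a
   correlation ≥ 0.98 between generating and re-estimated factor means.

Downstream, groups are ranked by aligned factor means and by conventional
prevalence with 99.9% confidence intervals, clustered by CI overlap, and the
two rankings are compared with an exact matched-pairs signed-rank test and
product-moment convergent-validity correlations.

## Worked example

```python
import numpy as np
from ipvalign import PipelineConfig, generate, run_full_study
from ipvalign.synthetic_data import invariance_benchmark_spec

spec = invariance_benchmark_spec(G=6, n_g=800, seed=17)   # fully invariant
table, truth = generate(spec)
report = run_full_study(table, PipelineConfig(mc_replications=5, seed=1))
```

Printing the report's summary quantities gives:

```
groups admitted by the adequacy gate: 6/6
exact-invariance ladder reached:      scalar
  metric against configural: chi2=38.2, df=30, p=0.144
  scalar against metric: chi2=19.8, df=30, p=0.921
non-invariant parameters: thresholds 2.4%, loadings 2.4%, all 2.4%  (trustworthy: True)
Monte-Carlo mean correlation: 0.995
AO ranking clusters: 3, prevalence clusters: 3
rank concordance (signed-rank): W+=2, p=1.00
corr(true, estimated factor means): 0.998
```

Reading this: all six synthetic groups pass the country-level adequacy gate;
because the generating model is fully invariant, the likelihood-ratio ladder
climbs to scalar invariance (both tests non-significant); alignment flags
only ~2% of parameters (well under the 25% trustworthiness limit); the
Monte-Carlo correlation of 0.995 exceeds the 0.98 reliability bound; and the
estimated factor means track the generating group means almost perfectly.

The same pipeline is available from the shell:

```bash
ipvalign simulate data.csv --item-set physical_ipv --groups 36 --n-per-group 500 --seed 1
ipvalign run-all data.csv --item-set physical_ipv --seed 1 --out report/
```

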