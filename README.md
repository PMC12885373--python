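# ampbias

**How PCR amplification bias distorts microbiome diversity analyses — and
which estimands are immune to it.**

Amplicon-based microbiome profiling amplifies marker genes (e.g. 16S rRNA)
over tens of PCR cycles, and templates amplify at different per-cycle
efficiencies *b_d* ∈ [1, 2].  After *x* cycles the observed ratio of two
templates is

```
w1/w2 = (a1/a2) · (b1/b2)^x
```

so in log-ratio coordinates (φ(π) = Ψ log π, with Ψ a contrast matrix whose
rows sum to zero) the bias is a constant additive shift:

```
φ(w) = φ(a) + x·β,        β = Ψ log b .
```

`ampbias` is a toolkit for microbiome researchers and method developers who
want to know what that shift does to ecological conclusions.  It provides:

* **Simulation** of calibration experiments (the same community sequenced at
  several PCR cycle numbers) from the multinomial logistic-normal hierarchy
  `Y_n ~ Multinomial(φ⁻¹(η_n))`, `η_n ~ N(ΛX_n, Σ)`, with ground truth for
  recovery tests.
* **Bayesian calibration**: the collapse → Laplace → uncollapse fit of the
  model, yielding joint posterior draws of each community's unamplified
  composition α and the shared per-cycle bias β = Ψ log b.
* **Diversity metrics**: Shannon, Gini–Simpson, Gini, Aitchison norm;
  Bray–Curtis, weighted UniFrac (with tree handling), Aitchison distance.
* **Bias estimands**: `f(φ⁻¹(α+35β)) − f(φ⁻¹(α))` and its β-diversity and
  relative analogues, propagated through the joint posterior.
* **Perturbation-invariance checking**: estimands unchanged when every
  sample's log-ratios receive the same shift — the differential log-ratio τ
  and the Aitchison distance — are provably immune to PCR bias; Shannon,
  Bray–Curtis, weighted UniFrac and friends are not.
* **Worst-case group distortion**: the binary grouping maximizing
  ΔR² = |R²₃₅ − R²₀| (ANOVA or PERMANOVA R²), by exhaustive search, genetic
  algorithm, or particle swarm.
* **Ternary bias surfaces** showing how bias depends on where a community
  sits in the 3-taxon simplex.

## Worked example

```python
import numpy as np
from ampbias import (
    mock_community_study, fit_mln, extract_alpha_beta, posterior_bias,
    check_invariance, alpha_estimand, beta_estimand,
)

# a synthetic calibration study: 10 taxa, 10 communities, replicates at
# 20/28/35 PCR cycles, 10,000 reads each, known efficiencies
study = mock_community_study(seed=42)
draws = fit_mln(study.counts, study.design, psi=study.psi, n_draws=500, seed=42)

_, beta_draws = extract_alpha_beta(draws, "community_01")
r = np.corrcoef(beta_draws.mean(axis=0), study.beta_true)[0, 1]
print(f"per-cycle bias recovery: Pearson r = {r:.3f}")

res = posterior_bias(draws, "community_01", "shannon", x=35)
print(f"Shannon bias after 35 cycles: {res.median:+.3f} [{res.lo95:+.3f}, {res.hi95:+.3f}]")

res2 = posterior_bias(draws, ("community_01", "community_02"), "aitchison_distance", x=35)
print(f"Aitchison-distance bias: {res2.median:+.1e}")

rng = np.random.default_rng(0)
comps = [rng.dirichlet(np.ones(10)) for _ in range(6)]
for metric, est in [("shannon", alpha_estimand("shannon")),
                    ("aitchison_distance", beta_estimand("aitchison_distance"))]:
    rep = check_invariance(est, comps, n_trials=1000, seed=0, name=metric)
    print(f"{metric}: {rep.verdict} (max |change| {rep.max_abs_deviation:.2e})")
```

prints

```
per-cycle bias recovery: Pearson r = 0.979
Shannon bias after 35 cycles: -0.654 [-0.949, -0.293]
Aitchison-distance bias: +0.0e+00
shannon: sensitive (max |change| 1.07e+00)
aitchison_distance: invariant (max |change| 5.33e-15)
```

Read: the fit recovers the true per-cycle bias vector almost perfectly
(r = 0.98); 35 cycles of amplification knock about 0.65 nats off this
community's Shannon diversity, with the 95% credible interval well away
from zero; the Aitchison distance between two communities is untouched to
machine precision; and randomized perturbation trials classify Shannon as
bias-sensitive and the Aitchison distance as bias-invariant.  On the same
fitted study, the worst-case grouping search
(`optimize_grouping(..., mode="anova", method="brute_force")`) finds a
split of the ten communities whose Shannon ANOVA R² moves from 0.01 at
cycle 0 to 0.81 at cycle 35 — ΔR² = 0.80 — showing how strongly PCR bias
can manufacture or destroy apparent group differences when the grouping
aligns with the bias direction.

The same analyses are available from a shell:

```bash
ampbias simulate --seed 42 --outdir results/demo
ampbias fit --counts results/demo/counts.tsv --metadata results/demo/metadata.tsv
ampbias invariance-check --metric aitchison_distance
ampbias sweep --metric shannon --beta 0.105,0 --plot surface.png
ampbias run --config config.yaml      # the full pipeline + manifest
```

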