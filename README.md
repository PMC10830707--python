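# isomix

Quantifying marine resource subsidies in the diets of shoreline consumers
from carbon and nitrogen stable isotopes.

Marine and terrestrial food webs differ predictably in δ¹³C and δ¹⁵N, so a
beach-dwelling predator's tissue records how much of its diet came from each
side of the shoreline.  `isomix` is a library for ecologists analyzing such
two-source systems — its motivating case is western fence lizards
(*Sceloporus occidentalis*) on Puget Sound beaches eating intertidal
wrack-associated amphipods alongside terrestrial arthropods — and provides:

* **Diet estimation, two ways.**  The algebraic α estimator,

  α = {[(δ¹³C_consumer − Δ¹³C) − δ¹³C_terrestrial] / (δ¹³C_marine − δ¹³C_terrestrial)} × 100,

  and a Bayesian two-source mixing model with a Dirichlet(1,1) prior on the
  diet proportions *p* = (p_marine, p_terrestrial) and, per isotope *i*,

  x_i ~ Normal( Σ_k p_k (μ_ki + Δ_i),  √(Σ_k p_k² (σ_ki² + σ_Δi²)) ),

  which propagates both source spread and trophic-discrimination (Δ)
  uncertainty.  Sampling is random-walk Metropolis on logit(p_marine) with
  multiple overdispersed chains and split-R̂ monitoring; a deterministic
  grid-quadrature routine computes the same posterior as an independent
  cross-check.

* **Isotopic niche breadth.**  Standard ellipse area SEA = π√(λ₁λ₂) from the
  sample covariance eigenvalues, the small-sample correction
  SEA_C = SEA·(n−1)/(n−2), and Bayesian posterior SEA draws under a conjugate
  normal–inverse-Wishart model.

* **Site-level statistics.**  Transition-zone hillslope summaries from
  transect elevation reliefs, simple OLS with the F test on (1, n−2) df,
  Kruskal–Wallis with Dunn (or Dunnett) post hocs, pooled-variance t-tests on
  log percent marine diet, Pearson correlations, C:N quality control, and
  body condition as residuals of mass ~ SVL³.

* **A ground-truthed synthetic study generator** that emulates the five-beach
  design (7–11 lizards per site, 9 marine + 8 terrestrial arthropod source
  samples, a logistic hillslope→subsidy link) so the whole pipeline is
  testable end to end with known answers.

## Worked example

Fit one beach lizard (δ¹³C = −16.4‰, δ¹⁵N = 6.9‰) against marine
(−10.0 ± 1.0‰, 9.0 ± 1.0‰) and terrestrial (−28.0 ± 1.5‰, 2.0 ± 1.5‰)
arthropod sources with claw discrimination (+1.2 ± 0.4‰, +0.7 ± 0.3‰):

```
$ python examples/02_bayesian_mixing.py
posterior mean marine fraction: 0.579 (SD 0.047)
95% credible interval:          [0.481, 0.671]
split-Rhat:                     0.9999 (converged <= 1.05)
grid-quadrature check:          0.580
```

This lizard derives ~58% of its diet from the marine food web; the sampler
and the independent quadrature agree to 0.001.  Regressing the published
five-site summary (`examples/04_site_regressions.py`) gives

```
percent marine diet ~ slope mean:  F=19.2 df=1,3 P=0.022 R2=0.86
SEA_C ~ slope SD:                  y = 1.88 + 21.16x, F=13.76 P=0.034 R2=0.82
```

— steeper shorelines carry stronger marine subsidies, and more variable
shorelines host broader isotopic niches.  `examples/05_full_pipeline.py` runs
the full synthetic pipeline and shows per-site recovery of the known true
marine fractions to within a few percentage points.

A thin CLI wraps the same library calls:

```
isomix simulate --seed 1 -o out/          # synthetic study CSVs + ground truth
isomix run --seed 1 -o out/               # simulate -> QC -> diet -> niche -> stats
isomix fit-diet consumers.csv -o diet.csv
isomix niche consumers.csv -o niche.csv
```

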