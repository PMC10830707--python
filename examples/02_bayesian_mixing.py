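"""Bayesian two-source mixing model for one consumer, with a quadrature check.

The model places a flat Dirichlet(1,1) prior on (p_marine, p_terrestrial) and
a normal likelihood per isotope whose mean and variance mix the
discrimination-adjusted source distributions.  The MCMC posterior mean is
compared against brute-force grid integration of the same posterior.
"""

from isomix import CLAW, MCMCConfig, fit_two_source_model, grid_posterior_mean
from isomix.records import IsotopeRecord, SourceDistribution

marine = SourceDistribution("marine", mu_C=-10.0, mu_N=9.0, sd_C=1.0, sd_N=1.0, n=9)
terrestrial = SourceDistribution("terrestrial", mu_C=-28.0, mu_N=2.0, sd_C=1.5, sd_N=1.5, n=8)

lizard = IsotopeRecord(sample_id="DM_L03", site="DM", habitat="beach",
                       tissue="lizard_tail", d13C=-16.4, d15N=6.9, cn_ratio=3.4)

est = fit_two_source_model(lizard, (marine, terrestrial), CLAW, MCMCConfig(seed=1))
grid = grid_posterior_mean(lizard, (marine, terrestrial), CLAW)

print(f"posterior mean marine fraction: {est.p_marine_mean:.3f} "
      f"(SD {est.p_marine_sd:.3f})")
print(f"95% credible interval:          [{est.ci_low:.3f}, {est.ci_high:.3f}]")
print(f"split-Rhat:                     {est.rhat:.4f} (converged <= 1.05)")
print(f"grid-quadrature check:          {grid:.3f}")

# The two routes should agree to ~0.01: the sampler and the deterministic
# integral are independent computations of the same posterior.
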