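"""State-dependent diversification: does a binary trait change the rates?

Simulates a BiSSE tree in which the derived state (anadromy) speciates much
faster than the ancestral freshwater state, fits constrained (equal-rate)
and unconstrained models by maximum likelihood, runs the likelihood-ratio
test, and summarises a short MCMC posterior sample.
"""

import salmodiv as sd

truth = sd.BisseParams(lam0=0.09, lam1=0.31, mu0=0.04, mu1=0.14, q01=0.01, q10=0.01)
tree, traits = sd.simulate_bisse(truth, n_tips=65, root_state=1, seed=4)
n1 = sum(traits.states.values())
print(f"simulated 65-tip tree: {n1} anadromous (state 1), {65 - n1} freshwater")

constrained = sd.bisse_ml(tree, traits, constrained=True, n_starts=3, seed=0)
free = sd.bisse_ml(
    tree, traits, n_starts=3, seed=0, extra_starts=[constrained.params]
)
print(f"constrained logL = {constrained.loglik:.2f} "
      f"(lambda = {constrained.params.lam0:.3f})")
print(f"free logL        = {free.loglik:.2f} "
      f"(lambda_F = {free.params.lam0:.3f}, lambda_A = {free.params.lam1:.3f})")

lrt = sd.bisse_lrt(free, constrained)
print(f"LRT: chi2 = {lrt.statistic:.2f}, df = {lrt.df}, p = {lrt.pvalue:.4f}")
# Rejecting the constrained model means tree shape + tip states are better
# explained by state-dependent speciation/extinction rates.

trace = sd.bisse_mcmc(tree, traits, n_steps=2000, seed=1)
for j, name in enumerate(trace.param_names[:2]):
    lo, hi = trace.ci95[j]
    print(f"posterior {name}: mean {trace.posterior_mean[j]:.3f} "
          f"95% CI [{lo:.3f}, {hi:.3f}]")
print(f"speciation-rate CIs overlap: {trace.ci_overlap['lambda']}")
# Non-overlapping lambda credibility intervals mirror the headline pattern:
# clearly higher speciation in the anadromous state.
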