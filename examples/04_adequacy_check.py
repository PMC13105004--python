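"""Posterior predictive adequacy: does the fitted model reproduce the data?

Fits the dysploidy-only model to a clade that actually evolved with strong
polyploidy, then checks whether simulated replicates reproduce the observed
count variance and entropy. Misspecification shows up as extreme p-values.
"""

import karyotempo as kt

tree = kt.simulate_yule_tree(100, seed=21)
space = kt.StateSpace(1, 60)
truth = kt.RateParams(gain=0.3, loss=0.3, poly=0.8)   # heavy polyploidy
counts, _ = kt.simulate_counts(tree, space, truth, root_state=6, seed=22)

sample = kt.run_mcmc(
    tree, counts, kt.DYSPLOIDY_ONLY,          # deliberately misspecified
    cfg=kt.MCMCConfig(n_steps=400, seed=23), space=space,
)
result = kt.posterior_predictive_check(tree, counts, sample,
                                       n_replicates=200, seed=24, space=space)
print(f"observed: variance {result.observed['variance']:.2f}, "
      f"entropy {result.observed['entropy']:.3f} nats")
for stat in ("variance", "entropy"):
    print(f"{stat}: PPP {result.ppp[stat]:.3f} "
          f"(two-sided {result.ppp_two_sided[stat]:.3f})")
# P(replicate >= observed) near 1/(n+1) or 1 means the model cannot reproduce
# that feature of the data; values in the middle indicate adequacy.
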