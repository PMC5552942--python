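"""Diet mixing: energy-group sources, posterior proportions, TEF sensitivity.

Clusters prey species into three energy groups on the (E*pi*R, A) plane,
builds isotopic sources from them, fits the Bayesian mixing model to the
predators of one habitat, and reports how the posterior means move across
the three trophic-enrichment presets.
"""
from engineerweb import (FoodWebSpec, RunConfig, abec_source_groups,
                         fit_mixing, generate_study, tef_sensitivity)

config = RunConfig(seed=6)
study = generate_study(FoodWebSpec(), config)

sources = abec_source_groups(study.coefficients, study.isotopes,
                             bay="BayA", habitat="Haploops")
print("energy-group sources (d13C, d15N means):")
for label, mean in zip(sources.labels, sources.means):
    print(f"  {label}: ({mean[0]:6.2f}, {mean[1]:5.2f})  "
          f"members = {len(sources.members[label])}")
print(f"flags: {sources.flags}")

predators = study.isotopes.data.query(
    "bay == 'BayA' and habitat == 'Haploops' and role == 'predator'")
consumers = predators[["d13C", "d15N"]].to_numpy()
post = fit_mixing(consumers, sources, tef="TEF3",
                  n_iter=12000, burn_in=6000, thin=5,
                  seed=config.stage_seed("example"))
print(f"\nposterior diet proportions ({len(consumers)} replicates, "
      f"converged = {post.converged}):")
print(post.percentiles.round(3).to_string())
print(f"preferred source: {post.preferred}")
# The generator feeds every predator 20/50/30% of the three prey guilds;
# the posterior median should put group2 (intermediate energy) on top.

sens = tef_sensitivity(consumers, sources, seed=1,
                       n_iter=8000, burn_in=4000, thin=5)
print("\nposterior means under each enrichment preset:")
print(sens.round(3).to_string())
# When the three sources sit close together in isotope space, shifting
# the enrichment assumption by half a permil re-attributes much of the
# diet -- the max_change row quantifies that sensitivity.
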