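"""Run the full statistical battery on a synthetic odonate community.

Generates a 49-pond metrics table (41 stormwater + 8 natural), draws a
negative-binomial community in which dragonfly abundance rises with
connectivity and one indicator dragonfly is concentrated at
high-connectivity natural ponds, then fits the 12 Gaussian models and
4 permutation-tested RDAs, plus pond-type Wilcoxon comparisons.
"""

from pondnet import (
    CommunityConfig,
    generate_community,
    generate_site_metrics,
    predictor_correlation,
    run_model_battery,
    wilcoxon_rank_sum,
)

sites, metrics = generate_site_metrics(n_sites=49, seed=31)
m900 = metrics[metrics["scale_m"] == 900.0].reset_index(drop=True)
community = generate_community(m900, CommunityConfig(n_sites=49, seed=32))

glm_df, rda_df = run_model_battery(metrics, community, seed=33)
cols = ["response", "predictor", "slope", "r_squared", "p_value"]
print(glm_df[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("-> dragonfly abundance/richness rise with mean current; damselfly rows"
      " stay flat or weakly negative, mirroring the assumed community structure")

print(rda_df[["suborder", "predictor", "adj_r_squared", "p_value", "top_species"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("-> the indicator dragonfly carries the largest positive species score"
      " on the connectivity-constrained axis")

r = predictor_correlation(m900["mean_current"], m900["n_neighbours"])
print(f"predictors are collinear (r = {r:.2f} at 900 m), hence one predictor per model")

nat = m900[m900["type"] == "natural"]["mean_current"]
sto = m900[m900["type"] == "stormwater"]["mean_current"]
w = wilcoxon_rank_sum(nat, sto)
print(f"natural vs stormwater mean current: W = {w['W']:.0f}, p = {w['p_value']:.2g}"
      f" ({w['method']}) - natural ponds sit in better-connected surroundings")
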