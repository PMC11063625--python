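"""Selectivity census: factorial ANOVA per neuron + bootstrap null.

Each neuron's stimulus-window counts enter a 2x2 emotion x memory ANOVA;
the number of selective neurons (E / M / X after interaction precedence) is
compared with counts obtained by re-running the same selection on
shuffled trial labels.
"""

from emomem import (
    CohortConfig, build_unit_counts, census_all, simulate_cohort,
    stratified_census,
)

cfg = CohortConfig(n_patients=3, units_per_region=8, phases=("encoding",),
                   frac_emotion=0.25, effect_gain_scale=2.0)
dataset, truth = simulate_cohort(cfg, seed=3)
data, excluded = build_unit_counts(
    dataset.units, dataset.trials["encoding"], "encoding"
)
print(f"{len(data)} analyzable units ({len(excluded)} with empty cells)")

census = census_all(data, B=2000, alpha=0.05, seed=0)
planted = sum(c == "emotion" for c in truth.unit_classes.values())
print(f"planted emotion units: {planted}")
for effect, res in census.items():
    print(f"effect {effect}: observed {res.observed_count:3d}, "
          f"null mean {res.null_counts.mean():5.1f}, p = {res.p:.4g}")
# The emotion census p-value collapses to the 1/B floor when the observed
# count beats every shuffled count; memory/interaction stay at chance.

strata = stratified_census(data, by="region", B=500, seed=0)
for region, res in strata.items():
    print(f"  {region}: E observed {res['E'].observed_count}, p = {res['E'].p:.3f}")
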