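"""Per-female traits, population means, and the patry statistical battery.

Runs trait extraction (count, areas, coverage, density, nearest-neighbor
spacing) on a synthetic study, averages technical replicates, aggregates to
population means, and prints the species and patry contrasts.
"""

from platemorph import RunConfig, run_pipeline

# min_n set high to skip the (slower) spatial/shape stages in this example
bundle = run_pipeline(RunConfig(seed=1, n_perm=99, min_n=10**6))

pop = bundle["population_means"]
print("population-mean traits (first rows):")
print(
    pop[["species", "population_id", "patry", "n_females", "sensilla_count",
         "coverage_proportion", "density"]].head(8).to_string(index=False)
)

print("\ntrait battery (count + coverage):")
battery = bundle["battery"]
sel = battery[battery.trait.isin(["sensilla_count", "coverage_proportion"])]
print(sel[["contrast", "trait", "test", "statistic", "df", "p_value"]].to_string(index=False))
# 'species' rows should reject strongly (planted difference); the patry
# contrasts should not (no displacement effect is planted by default).
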