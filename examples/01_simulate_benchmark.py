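"""Generate a synthetic drug-combination benchmark and look inside it.

Builds a universe of drugs with four attribute sources (DDI graph, ATC
codes, target profiles, side-effect profiles) and a small positive class
of combinative pairs with planted signal, then prints summary statistics.
"""

from combifuse import SyntheticConfig, generate, write_fixture

config = SyntheticConfig()  # default study conditions, effect_strength = 4
universe, network, labels = generate(config, seed=1)

print(f"drugs:              {universe.m}")
print(f"DDI edges:          {network.n_edges}")
print(f"targets / SEs:      {len(universe.dti_items)} / {len(universe.se_items)}")
print(f"positive pairs:     {labels.n_positives}")
print(f"candidate pairs:    {len(labels.scope)}  (= m(m-1)/2)")
mean_atc = sum(len(s) for s in universe.atc_sets.values()) / universe.m
print(f"mean ATC set size:  {mean_atc:.2f}")

paths = write_fixture(universe, network, labels, "scratch/example_benchmark")
print(f"wrote TSV fixture:  {sorted(p.name for p in paths.values())}")

# The positive pairs are the 'approved combinations'; every other pair in
# scope is treated as a negative instance by the evaluation protocols.
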