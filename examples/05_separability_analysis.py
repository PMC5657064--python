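"""Channel-wise separability of positive vs negative drug pairs.

For each feature channel a statistic in [0, 1] summarises how well
approved combinations stand apart from other pairs: graph distance for
DDI, first-level code sharing for ATC, and per-feature occurrence
frequencies for SE/DTI. 0.5 means no separation.
"""

import json

from combifuse import generate, separability_report

universe, network, labels = generate(seed=1)
report = separability_report(universe, network, labels)

print(json.dumps(report.as_dict(), indent=2))
print()
print("Reading: positives sit at DDI distance 2 more often than negatives,")
print("share first-level ATC codes more often, and avoid the side-effect /")
print("target features that are enriched among negative pairs.")
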