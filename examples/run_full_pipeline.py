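"""Run the whole analysis end to end on a synthetic study and score it
against the planted truth.

The planted design mirrors the motivating study: a 365-assay miRNA panel on
3 pooled-reference replicates + 8 patient pairs, a 2 000-probe expression
array, 10 miRNA with |log2 FC| = 2 lesion effects, 50 independently
dysregulated genes, and 20 miRNA:probe pairs negatively coupled with slope
-0.8. Three simulated prediction programs emit the coupled pairs plus 10%
decoys each.
"""

import json

from dcismir import PipelineConfig, run_all
from dcismir.simulate import planted_design

cfg = PipelineConfig()
run = run_all(cfg, design=planted_design(seed=7))

print("stage counts:")
print(json.dumps(run.manifest.counts, indent=2))
print("\nrecovery against planted truth:")
print(json.dumps(run.recovery, indent=2))

# What the numbers mean: `mirna_significant` counts features with p < 0.005
# in at least one comparison; `pairs_retained` are prediction-intersection
# pairs whose miRNA and gene both passed their differential-expression
# stages; the pair F1 compares those against the 20 planted couplings —
# near 1.0 means the integration chain recovered essentially all of them
# with almost no decoys.
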