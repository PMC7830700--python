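"""The complete offline chain, at the default benchmark scale.

Generates the full synthetic corpus (30 trials of 20 s per motion),
trains the network on a 70/30 split, decodes the three alternating test
sequences (RE, RS, SF), applies the state-exclusion filter, and drives
the simulated plant.  The summary prints per-class and mean accuracy
before and after filtering — the filter can only preserve or improve
the mean — and the number of motion loops recognized per sequence
(10 segments = 5 loops each when decoding is perfect).
"""

from semglove import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
print(result.summary())
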