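"""Run the whole in-silico experiment: simulate -> detect -> pool -> stats.

Two conditions (WT-like and KO-like, 5 neurons each, explicit seeds) are
simulated and analyzed end to end; the result bundle (events.csv,
release.csv, cumulative curves, stats report, ground truth, manifest)
is written to ./scratch/example_run.
"""

import numpy as np

from vesiclefuse.pipeline import ConditionRun, RunConfig, run_experiment

cfg = RunConfig(
    conditions=(ConditionRun("WT", "WT-like", seed=101, n_neurons=5),
                ConditionRun("KO", "KO-like", seed=202, n_neurons=5)),
    out_dir="scratch/example_run",
)
bundle = run_experiment(cfg)

release = bundle["release"]
for cond, block in release.groupby("condition"):
    print(f"{cond}: median events {block.n_events.median():.1f}, "
          f"median pool {block.n_pool.median():.0f}, "
          f"median released fraction {np.nanmedian(block.released_fraction):.3f}")
ratio = (release[release.condition == 'KO'].n_events.median()
         / release[release.condition == 'WT'].n_events.median())
print(f"KO / WT median event ratio: {ratio:.2f} (simulated fold change 3.0)")
print(f"stats: {bundle['stats']['test']} p = {bundle['stats']['p_value']:.3g}")
# Rerunning with the same config reproduces every CSV byte for byte.
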