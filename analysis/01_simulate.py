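#!/usr/bin/env python
"""Generate the synthetic six-run screening dataset.

Emulates the study conditions: 200 arrays in six processing runs (four pure
histology runs of 36, two mixed runs of 28), planted case-reactive antigens
(2% at a log2(1.5) = 0.585 class difference), per-run location/scale batch
effects and a two-session super-structure.  2000 features keep the
downstream scripts fast; the array count and design are at full study scale.

Writes: results/annotation.tsv, results/ground_truth.json,
        scratch/spots.tsv (large; spot-level, duplicates + controls).
"""

import argparse
from pathlib import Path

from lungsig import SimulationConfig, simulate_dataset
from lungsig.simulate import write_annotation

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-features", type=int, default=2000)
args = parser.parse_args()

root = Path(__file__).resolve().parents[1]
results = root / "results"
scratch = root / "scratch"
results.mkdir(exist_ok=True)
scratch.mkdir(exist_ok=True)

cfg = SimulationConfig(n_features=args.n_features, seed=args.seed)
spots, annotation, truth = simulate_dataset(cfg)

spots.to_csv(scratch / "spots.tsv", sep="\t", index=False)
write_annotation(annotation, results / "annotation.tsv")
truth.to_json(results / "ground_truth.json")

n_runs = annotation["run"].nunique()
print(f"simulated {len(annotation)} arrays in {n_runs} runs, "
      f"{args.n_features} features ({len(truth.reactive_feature_ids)} reactive), "
      f"{len(spots)} spots incl. duplicates and controls")
print(f"wrote {scratch / 'spots.tsv'} and {results / 'annotation.tsv'}")
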