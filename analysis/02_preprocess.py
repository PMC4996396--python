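#!/usr/bin/env python
"""Preprocess the spot table into a complete log2 intensity matrix.

Applies the study's rules: intensity floor 100, log2 transform, duplicate
averaging (flagged spots treated as missing), exclusion of features flagged
on >= 50% of arrays or constant at the floor, then feature-wise 10-NN
imputation of the remaining gaps.

Reads scratch/spots.tsv (from 01); writes results/matrix_raw.tsv.
"""

from pathlib import Path

import pandas as pd

from lungsig import preprocess_spot_table
from lungsig.preprocess import write_matrix

root = Path(__file__).resolve().parents[1]
spots_path = root / "scratch" / "spots.tsv"
if not spots_path.exists():
    raise SystemExit("run analysis/01_simulate.py first (scratch/spots.tsv missing)")
spots = pd.read_csv(spots_path, sep="\t")

matrix, dropped = preprocess_spot_table(spots)
write_matrix(matrix, root / "results" / "matrix_raw.tsv")

print(f"matrix: {matrix.shape[0]} features x {matrix.shape[1]} arrays "
      f"({len(dropped)} features excluded: flag filter or constant at floor)")
print(f"wrote {root / 'results' / 'matrix_raw.tsv'}")
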