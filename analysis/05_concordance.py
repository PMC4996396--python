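#!/usr/bin/env python
"""Class comparison and single-run vs cross-run concordance per method.

For every histology, the significant-antigen list (p < 0.001) from its
dedicated run is compared with the list from the combined two-run analysis;
the intersection-over-union overlap ranks the adjustment strategies: a
method that handles batch effects well keeps single-run findings alive
after the merge.

Reads results/matrix_*.tsv; writes results/concordance_overlap.tsv,
results/significant_counts.tsv and results/method_pairwise.json.
"""

import json
from pathlib import Path

from lungsig import concordance_table
from lungsig.preprocess import read_matrix
from lungsig.simulate import read_annotation

root = Path(__file__).resolve().parents[1]
results = root / "results"
annotation = read_annotation(results / "annotation.tsv")
matrices = {
    method: read_matrix(results / f"{stem}.tsv")
    for method, stem in (("unnormalized", "matrix_raw"), ("qnorm", "matrix_qnorm"),
                         ("combat", "matrix_combat"), ("dwd", "matrix_dwd"))
}

report = concordance_table(matrices, annotation)
report.overlap.to_csv(results / "concordance_overlap.tsv", sep="\t",
                      index_label="method")
report.counts.to_csv(results / "significant_counts.tsv", sep="\t", index=False)
(results / "method_pairwise.json").write_text(
    json.dumps(report.method_pairwise, indent=2)
)

print("single-run vs cross-run overlap (%):")
print(report.overlap.to_string())
best = report.overlap.mean(axis=1).idxmax()
print(f"\nhighest mean concordance: {best} "
      f"({report.overlap.mean(axis=1).max():.1f}%)")
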