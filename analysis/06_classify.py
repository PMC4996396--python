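#!/usr/bin/env python
"""Cross-validated classifier panels per histology and adjustment method.

Complete leave-one-out cross-validation (feature selection re-run inside
every fold) on each histology's two-run sample set, for quantile-normalized
and ComBat-adjusted data, plus the all-cases-vs-all-controls setting.
Reports correct classification rate, sensitivity and specificity, and the
four-set Venn overlap of the per-histology consensus panels.

Reads results/matrix_*.tsv; writes results/class_prediction.tsv and
results/classifier_venn.json.
"""

import json
from pathlib import Path

import pandas as pd

from lungsig import CvSpec, classifier_overlap_venn, loocv_class_prediction
from lungsig.design import CROSS_RUN_PAIRS, HISTOLOGIES
from lungsig.preprocess import read_matrix
from lungsig.simulate import read_annotation

root = Path(__file__).resolve().parents[1]
results = root / "results"
annotation = read_annotation(results / "annotation.tsv")
matrices = {"qnorm": read_matrix(results / "matrix_qnorm.tsv"),
            "combat": read_matrix(results / "matrix_combat.tsv")}

spec = CvSpec(feature_selection="greedy_pairs", selected_size=25, model="DLDA")
rows, panels = [], {}
for method, matrix in matrices.items():
    for hist in HISTOLOGIES:
        runs = CROSS_RUN_PAIRS[hist]
        sub = annotation[annotation["run"].isin(runs)]
        keep = (sub["histology"] == hist) | (sub["class"] == "control")
        labels = sub.loc[keep, "class"]
        perf = loocv_class_prediction(matrix[labels.index], labels, spec)
        rows.append({"sample_set": hist, "method": method,
                     **{k: round(v, 3) if isinstance(v, float) else v
                        for k, v in perf.summary().items()}})
        if method == "combat":
            panels[hist] = perf.consensus_features
    labels_all = annotation["class"]
    perf = loocv_class_prediction(matrix, labels_all, spec)
    rows.append({"sample_set": "all", "method": method,
                 **{k: round(v, 3) if isinstance(v, float) else v
                    for k, v in perf.summary().items()}})

table = pd.DataFrame(rows)
table.to_csv(results / "class_prediction.tsv", sep="\t", index=False)
venn = classifier_overlap_venn(panels)
(results / "classifier_venn.json").write_text(json.dumps(venn, indent=2))

print(table.to_string(index=False))
shared = {k: v for k, v in venn.items() if "&" in k and v > 0}
print(f"\nhistology panels share few antigens: {shared or 'no overlapping regions'}")
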