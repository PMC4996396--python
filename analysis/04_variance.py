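#!/usr/bin/env python
"""PCA visualization and PVCA variance attribution per adjustment method.

Quantifies how much of the total variance each known factor (run, sample
type, sex, age group, smoking, pairwise combinations) explains before and
after each adjustment; the run component is the batch-effect yardstick.

Reads results/matrix_*.tsv; writes results/pvca.tsv and figures under
scratch/figures/.
"""

from pathlib import Path

import pandas as pd

from lungsig import pca_scores, pvca
from lungsig.plots import plot_pca_runs, plot_pvca_bars
from lungsig.preprocess import read_matrix
from lungsig.simulate import read_annotation

root = Path(__file__).resolve().parents[1]
results = root / "results"
figures = root / "scratch" / "figures"
figures.mkdir(parents=True, exist_ok=True)
annotation = read_annotation(results / "annotation.tsv")

rows = []
for method, stem in (("unnormalized", "matrix_raw"), ("qnorm", "matrix_qnorm"),
                     ("combat", "matrix_combat"), ("dwd", "matrix_dwd")):
    matrix = read_matrix(results / f"{stem}.tsv")
    pca = pca_scores(matrix, n_components=3)
    plot_pca_runs(pca, annotation, figures / f"pca_{method}.png", title=method)
    res = pvca(matrix, annotation, var_threshold=0.60)
    plot_pvca_bars(res, figures / f"pvca_{method}.png", title=method)
    for factor, prop in res.proportions.items():
        rows.append({"method": method, "factor": factor,
                     "proportion_pct": round(100 * prop, 3)})
    run_pct = 100 * res.proportions["run"]
    resid_pct = 100 * res.proportions["resid"]
    print(f"{method:>12s}: run = {run_pct:6.2f}%  resid = {resid_pct:5.1f}%  "
          f"({res.n_components} PCs to 60% variance)")

pd.DataFrame(rows).to_csv(results / "pvca.tsv", sep="\t", index=False)
print(f"wrote {results / 'pvca.tsv'} and figures under {figures}")
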