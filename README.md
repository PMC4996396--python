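# lungsig

Batch-effect-aware analysis of autoantibody protein-microarray screens,
built around a lung-cancer immune-signature study design: 100 cases (25
each of SCLC, SqLC, LCLC, AdCa) and 100 matched controls probed on a 16k
recombinant-protein array, processed in six daily runs that double as
batches.  The package is for bioinformaticians who need to decide **how to
normalize multi-batch antibody-reactivity data before biomarker
discovery** — and to verify, on data with known ground truth, that their
choice preserves findings instead of manufacturing them.

It provides, as one tested pipeline:

- a **synthetic-data generator** for the six-run design with planted
  case-reactive antigens, per-run location/scale batch effects
  (γ<sub>ig</sub>, δ<sub>ig</sub> — exactly the model ComBat assumes), a
  two-session super-structure, duplicate spots, flags and control spots,
  plus GPR-dialect readers/writers for GenePix-style exports;
- **preprocessing**: intensity floor 100 → log2 → duplicate averaging →
  ≥ 50% flag exclusion → feature-wise 10-NN imputation;
- three **adjustment strategies**: quantile normalization, parametric
  empirical-Bayes **ComBat**, and stepwise pairwise **DWD** merging along a
  run tree;
- **PCA/PVCA**: principal variance components analysis attributing
  variance to run, sample type, sex, age, smoking and pairwise
  interactions via eigenvalue-weighted REML variance components;
- **class comparison** (per-antigen pooled t-tests at p < 0.001) with the
  single-run vs cross-run **concordance** criterion
  (overlap % = 100·|A∩B|/|A∪B|) for ranking adjustment methods;
- **classifier panels** with complete leave-one-out cross-validation
  (greedy-pairs and SVM-RFE selection re-run inside every fold; CCP, DLDA,
  k-NN, nearest-centroid, linear SVM and Bayesian-CCP models), reporting
  correct classification rate, sensitivity, specificity and panel Venn
  overlaps.

See `docs/methods.md` for the models, estimators and their assumptions.

## Worked example

```python
from lungsig import (SimulationConfig, simulate_dataset, preprocess_spot_table,
                     combat_adjust, pvca, concordance_table)

cfg = SimulationConfig(n_features=2000, seed=1)   # six runs, 200 arrays
spots, annotation, truth = simulate_dataset(cfg)
matrix, dropped = preprocess_spot_table(spots)    # complete log2 matrix
adjusted = combat_adjust(matrix, annotation["run"])

raw = pvca(matrix, annotation)
fixed = pvca(adjusted, annotation)
print(f"run variance share: raw {100*raw.proportions['run']:.1f}% "
      f"-> ComBat {100*fixed.proportions['run']:.2f}%")

rep = concordance_table({"unnormalized": matrix, "combat": adjusted}, annotation)
print(rep.overlap)
```

Output (seed 1):

```
run variance share: raw 90.2% -> ComBat 0.00%
              SCLC  SqLC  LCLC  AdCa
unnormalized  80.0  68.4  57.6  38.7
combat        67.6  69.2  57.1  63.6
```

Reading: the planted per-run batch effects dominate the raw data (90% of
weighted variance), and ComBat removes that component entirely.  The
second table is the single-run vs cross-run concordance — the percentage
of significant antigens (p < 0.001) from a one-run analysis that survive
when the second run of the same histology is merged in.  Averaged over
histologies ComBat retains the most findings (64.4%); the unnormalized
AdCa cell collapses (38.7%) because in the mixed runs the case:control
ratio differs and uncorrected batch effects partially confound class.

The same steps are available as numbered drivers
(`analysis/01_simulate.py` … `analysis/06_classify.py`, each `--seed`-able,
writing tables under `results/` and figures under `scratch/figures/`) and
as a CLI (`lungsig simulate|preprocess|adjust|pvca|compare|predict|all`).

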