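"""End-to-end study replica under one config.

simulate (or load .gpr files) -> preprocess -> adjust by each requested
method -> PVCA per method -> single-run vs cross-run concordance ->
cross-validated classifier panels -> consolidated report.  One seed drives
every stochastic stage; stage seeds are derived from it with
numpy.random.SeedSequence so stages stay reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, combat, compare, decompose, dwd, normalize, preprocess
from .simulate import SimulationConfig, simulate_dataset

METHODS = ("unnormalized", "qnorm", "combat", "dwd")


@dataclass
class CvEntry:
    """One classifier evaluation request (sample set x method x model)."""

    sample_set: str = "all"  # 'all' or a histology
    method: str = "combat"
    feature_selection: str = "greedy_pairs"
    selected_size: int = 25
    model: str = "DLDA"
    k: int = 3


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_gpr_dir: str | None = None
    input_annotation: str | None = None
    floor: float = preprocess.INTENSITY_FLOOR
    max_flag_frac: float = 0.5
    knn_k: int = preprocess.KNN_NEIGHBORS
    methods: tuple[str, ...] = METHODS
    pvca_threshold: float = 0.60
    alpha: float = compare.ALPHA
    cv: list[CvEntry] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; pick from {METHODS}")
        if self.input_gpr_dir is not None and not Path(self.input_gpr_dir).is_dir():
            raise FileNotFoundError(self.input_gpr_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cv = [CvEntry(**entry) for entry in raw.pop("cv", [])]
        cfg = cls(simulation=sim, cv=cv, **raw)
        if "methods" in raw:
            cfg.methods = tuple(raw["methods"])
        return cfg


def adjust_matrix(
    method: str,
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Dispatch one adjustment strategy on a complete log2 matrix."""
    if method == "unnormalized":
        return matrix.copy()
    if method == "qnorm":
        return normalize.quantile_normalize(matrix)
    if method == "combat":
        return combat.combat_adjust(matrix, annotation["run"])
    if method == "dwd":
        runs = annotation["run"]
        present = sorted(int(r) for r in runs.unique())
        plan = dwd.DEFAULT_MERGE_PLAN if present == [1, 2, 3, 4, 5, 6] else _chain_plan(present)
        return dwd.dwd_stepwise_merge(matrix, runs, merge_plan=plan)
    raise ValueError(f"unknown method {method!r}")


def _chain_plan(runs: list[int]):
    plan = runs[0]
    for r in runs[1:]:
        plan = (plan, r)
    return plan


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all requested stages; returns the in-memory report bundle."""
    config.validate()
    bundle: dict = {"config": _config_dict(config), "stages": []}

    if config.input_gpr_dir is not None:
        from .gpr import read_gpr_directory
        from .simulate import read_annotation

        spot_table = read_gpr_directory(config.input_gpr_dir)
        annotation = read_annotation(config.input_annotation)
        truth = None
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        spot_table, annotation, truth = simulate_dataset(sim)
    bundle["stages"].append("simulate" if truth is not None else "load")

    matrix, dropped = preprocess.preprocess_spot_table(
        spot_table,
        floor=config.floor,
        max_flag_frac=config.max_flag_frac,
        k=config.knn_k,
    )
    bundle["dropped_features"] = dropped
    bundle["stages"].append("preprocess")

    matrices = {m: adjust_matrix(m, matrix, annotation) for m in config.methods}
    bundle["stages"] += [f"adjust:{m}" for m in config.methods]

    bundle["pvca"] = {}
    for m, mat in matrices.items():
        res = decompose.pvca(mat, annotation, var_threshold=config.pvca_threshold)
        bundle["pvca"][m] = {
            "proportions": res.proportions,
            "n_components": res.n_components,
        }
    bundle["stages"].append("pvca")

    report = compare.concordance_table(matrices, annotation, alpha=config.alpha)
    bundle["concordance"] = {
        "overlap": report.overlap.to_dict(),
        "counts": report.counts.to_dict(orient="records"),
        "method_pairwise": report.method_pairwise,
        "notes": report.notes,
    }
    bundle["stages"].append("compare")

    bundle["class_prediction"] = []
    for entry in config.cv:
        mat = matrices[entry.method]
        if entry.sample_set == "all":
            labels = annotation["class"]
            cols = list(mat.columns)
        else:
            from .design import CROSS_RUN_PAIRS

            runs = CROSS_RUN_PAIRS[entry.sample_set]
            ann = annotation[annotation["run"].isin(runs)]
            keep = (ann["histology"] == entry.sample_set) | (ann["class"] == "control")
            labels = ann.loc[keep, "class"]
            cols = list(labels.index)
        spec = classify.CvSpec(
            feature_selection=entry.feature_selection,
            selected_size=entry.selected_size,
            model=entry.model,
            k=entry.k,
            seed=config.seed,
        )
        perf = classify.loocv_class_prediction(mat[cols], labels, spec)
        bundle["class_prediction"].append(
            {
                "sample_set": entry.sample_set,
                "method": entry.method,
                **perf.summary(),
                "consensus_features": perf.consensus_features,
            }
        )
    if config.cv:
        bundle["stages"].append("predict")
    bundle["matrices"] = matrices
    bundle["annotation"] = annotation
    if truth is not None:
        bundle["truth"] = truth
    return bundle


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["simulation"].pop("run_design", None)
    return d


def report(bundle: dict, directory: str | Path) -> list[Path]:
    """Write the bundle as stable-named TSV/JSON files plus a markdown summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def dump_json(name: str, payload) -> None:
        path = directory / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable))
        written.append(path)

    for m, mat in bundle.get("matrices", {}).items():
        path = directory / f"matrix_{m}.tsv"
        preprocess.write_matrix(mat, path)
        written.append(path)
    if "annotation" in bundle:
        path = directory / "annotation.tsv"
        bundle["annotation"].to_csv(path, sep="\t")
        written.append(path)
    if "pvca" in bundle:
        dump_json("pvca.json", bundle["pvca"])
        rows = [
            {"method": m, "factor": f, "proportion": p}
            for m, res in bundle["pvca"].items()
            for f, p in res["proportions"].items()
        ]
        path = directory / "pvca.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    if "concordance" in bundle:
        dump_json("concordance.json", bundle["concordance"])
        path = directory / "concordance_overlap.tsv"
        pd.DataFrame(bundle["concordance"]["overlap"]).to_csv(
            path, sep="\t", index_label="method"
        )
        written.append(path)
    if bundle.get("class_prediction"):
        dump_json("class_prediction.json", bundle["class_prediction"])
        path = directory / "class_prediction.tsv"
        pd.DataFrame(
            [
                {k: v for k, v in row.items() if k != "consensus_features"}
                for row in bundle["class_prediction"]
            ]
        ).to_csv(path, sep="\t", index=False)
        written.append(path)
    dump_json("run_summary.json", {
        "stages": bundle.get("stages", []),
        "config": bundle.get("config", {}),
        "n_dropped_features": len(bundle.get("dropped_features", [])),
    })
    written.append(_write_markdown(bundle, directory))
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_markdown(bundle: dict, directory: Path) -> Path:
    lines = ["# Pipeline summary", ""]
    if "pvca" in bundle:
        lines += ["## PVCA: weighted proportion of variance per factor", ""]
        for m, res in bundle["pvca"].items():
            top = sorted(res["proportions"].items(), key=lambda kv: -kv[1])[:4]
            desc = ", ".join(f"{f}={100 * p:.1f}%" for f, p in top)
            lines.append(f"- **{m}** ({res['n_components']} PCs): {desc}")
        lines.append("")
    if "concordance" in bundle:
        lines += ["## Single-run vs cross-run overlap (%)", ""]
        overlap = pd.DataFrame(bundle["concordance"]["overlap"])
        lines.append(overlap.to_markdown())
        lines.append("")
    if bundle.get("class_prediction"):
        lines += ["## Class prediction (complete LOOCV)", ""]
        for row in bundle["class_prediction"]:
            lines.append(
                f"- {row['sample_set']} / {row['method']} / {row['selection']}"
                f"({row['size']}) / {row['model']}: CC={100 * row['cc']:.0f}%, "
                f"sens={row['sensitivity']:.2f}, spec={row['specificity']:.2f}"
            )
        lines.append("")
    path = directory / "summary.md"
    path.write_text("\n".join(lines))
    return path
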