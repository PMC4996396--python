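"""Synthetic 16k protein-microarray generator.

Emulates the statistical structure the downstream analysis assumes: a
location/scale batch model on log2 intensities (the generative model ComBat
fits), a planted subset of case-reactive antigens, the two-session
super-structure of the six processing runs, duplicate spot printing,
flagged/missing spots, and on-slide positive/negative control spots.

The model for the log2 intensity of feature g on array j in run i is

    y_gj = mu_g + covariate shifts + effect * 1[case and g reactive]
           + session_i + gamma_ig + delta_ig * eps_gj,

with eps ~ N(0, noise_sd^2), gamma_ig ~ N(0, batch_add_sd^2) and
delta_ig^2 drawn from an inverse-gamma with mean 1 (ComBat's parametric
prior family, so the batch adjuster's assumptions hold exactly).  Each
feature is emitted as two duplicate spots that add independent
N(0, duplicate_sd^2) printing noise; spot tables carry raw-scale (2^y)
intensities so the floor -> log2 preprocessing round-trips the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import HISTOLOGIES, design_totals, session_of_run, table2_design

#: Positive-control printing concentrations (mg/mL E. coli lysate) and the
#: number of spots per concentration (281 positives, 82 negatives per slide).
POSITIVE_CONTROL_CONCS = (0.3, 0.4, 0.5)
POSITIVE_CONTROL_COUNTS = (94, 94, 93)
NEGATIVE_CONTROL_COUNT = 82

SPOT_COLUMNS = [
    "array_id",
    "spot_id",
    "feature_id",
    "intensity",
    "flag",
    "control_type",
    "control_conc",
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    noise_sd defaults to 0.414, the 50th percentile of the within-class
    log2 SD distribution used by the study's sample-size calculation;
    effect_log2 = 0.585 is log2(1.5), the class difference that calculation
    assumed; duplicate_sd = 0.15 reproduces the observed duplicate-spot
    concordance (Pearson r ~ 0.98).
    """

    n_features: int = 5449
    frac_reactive: float = 0.02
    effect_log2: float = 0.585
    run_design: dict[int, dict] | None = None
    batch_add_sd: float = 0.5
    batch_mult_shape: float | None = 30.0
    session_shift: float = 0.5
    noise_sd: float = 0.414
    duplicate_sd: float = 0.15
    missing_rate: float = 0.01
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.2
    seed: int = 0

    def resolved_design(self) -> dict[int, dict]:
        return self.run_design if self.run_design is not None else table2_design()

    def validate(self) -> None:
        if self.n_features < 10:
            raise ValueError(f"n_features must be >= 10, got {self.n_features}")
        if not 0.0 <= self.frac_reactive <= 1.0:
            raise ValueError("frac_reactive must lie in [0, 1]")
        for name in ("batch_add_sd", "noise_sd", "duplicate_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        design = self.resolved_design()
        if not design:
            raise ValueError("run design is empty")
        for run, grp in design.items():
            if sum(grp["cases"].values()) + grp["controls"] <= 0:
                raise ValueError(f"run {run} has no arrays")


@dataclass
class GroundTruth:
    """Planted parameters of a simulated dataset: the parameter-recovery oracle."""

    reactive_feature_ids: list[str]
    gamma: pd.DataFrame  # run x feature additive batch effects
    delta: pd.DataFrame  # run x feature multiplicative batch effects
    session: dict[int, float]  # per-run additive session offset
    baseline: pd.Series  # per-feature mean log2 intensity

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reactive_feature_ids": list(self.reactive_feature_ids),
            "gamma": self.gamma.to_dict(orient="index"),
            "delta": self.delta.to_dict(orient="index"),
            "session": {str(k): v for k, v in self.session.items()},
            "baseline": self.baseline.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        gamma = pd.DataFrame.from_dict(payload["gamma"], orient="index")
        gamma.index = gamma.index.astype(int)
        delta = pd.DataFrame.from_dict(payload["delta"], orient="index")
        delta.index = delta.index.astype(int)
        return cls(
            reactive_feature_ids=payload["reactive_feature_ids"],
            gamma=gamma,
            delta=delta,
            session={int(k): v for k, v in payload["session"].items()},
            baseline=pd.Series(payload["baseline"]),
        )


# Covariate frequencies mirror the clinical table of the screening cohort:
# both classes are ~69% male; smoking differs between cases and controls.
_SEX_P_MALE = {"case": 0.69, "control": 0.69}
_SMOKING_P = {
    "case": {"never": 0.06, "former": 0.49, "current": 0.45},
    "control": {"never": 0.24, "former": 0.42, "current": 0.34},
}
AGE_GROUPS = ("0-56", "56-64", "64-70", "70-100")


def build_annotation(run_design: dict[int, dict], rng: np.random.Generator) -> pd.DataFrame:
    """Sample a per-array annotation table for a run design.

    Covariates are drawn per array from the cohort's marginal frequencies;
    the generator applies no covariate effect by default, so these columns
    matter only as PVCA factors.
    """
    rows = []
    for run in sorted(run_design):
        grp = run_design[run]
        members: list[tuple[str, str]] = []
        for hist in sorted(grp["cases"], key=lambda h: HISTOLOGIES.index(h) if h in HISTOLOGIES else 99):
            members += [("case", hist)] * grp["cases"][hist]
        members += [("control", "none")] * grp["controls"]
        for k, (cls, hist) in enumerate(members, start=1):
            sex = "male" if rng.random() < _SEX_P_MALE[cls] else "female"
            smoking = rng.choice(
                list(_SMOKING_P[cls]), p=list(_SMOKING_P[cls].values())
            )
            age_group = rng.choice(AGE_GROUPS)
            rows.append(
                {
                    "array_id": f"run{run}_a{k:02d}",
                    "class": cls,
                    "histology": hist,
                    "run": run,
                    "sex": sex,
                    "age_group": str(age_group),
                    "smoking": str(smoking),
                }
            )
    return pd.DataFrame(rows).set_index("array_id")


def _covariate_shift(annotation: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    """Per-array additive log2 shift from 'column=level' keyed covariate effects."""
    shift = np.zeros(len(annotation))
    for key, value in effects.items():
        column, _, level = key.partition("=")
        if column not in annotation.columns:
            raise KeyError(f"unknown covariate column {column!r}")
        shift += value * (annotation[column].astype(str) == level).to_numpy()
    return shift


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a spot table, its annotation and the planted ground truth.

    Returns
    -------
    spot_table : long DataFrame with one row per printed spot (duplicates and
        control spots included); ``intensity`` is on raw fluorescence scale.
    annotation : per-array metadata indexed by array_id.
    truth : :class:`GroundTruth` with the planted batch and effect parameters.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = cfg.resolved_design()
    runs = sorted(design)

    feature_ids = [f"Ag{i + 1:05d}" for i in range(cfg.n_features)]
    n_reactive = round(cfg.frac_reactive * cfg.n_features)
    reactive_idx = rng.choice(cfg.n_features, size=n_reactive, replace=False)
    reactive = np.zeros(cfg.n_features, dtype=bool)
    reactive[reactive_idx] = True

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_features)

    gamma = {
        run: rng.normal(0.0, cfg.batch_add_sd, cfg.n_features) for run in runs
    }
    if cfg.batch_mult_shape is None:
        delta = {run: np.ones(cfg.n_features) for run in runs}
    else:
        shape = cfg.batch_mult_shape
        if shape <= 1:
            raise ValueError("batch_mult_shape must exceed 1 (mean-1 inverse gamma)")
        delta = {
            run: np.sqrt(
                stats.invgamma.rvs(shape, scale=shape - 1, size=cfg.n_features, random_state=rng)
            )
            for run in runs
        }
    session = {
        run: cfg.session_shift * (0.5 - session_of_run(run, runs)) for run in runs
    }

    annotation = build_annotation(design, rng)
    cov_shift = _covariate_shift(annotation, cfg.covariate_effects)
    is_case = (annotation["class"] == "case").to_numpy()

    frames = []
    for j, array_id in enumerate(annotation.index):
        run = int(annotation["run"].iloc[j])
        mean = baseline + gamma[run] + session[run] + cov_shift[j]
        if is_case[j]:
            mean = mean + cfg.effect_log2 * reactive
        y = mean + delta[run] * rng.normal(0.0, cfg.noise_sd, cfg.n_features)
        dup = y[:, None] + rng.normal(0.0, cfg.duplicate_sd, (cfg.n_features, 2))
        values = np.exp2(dup).ravel()  # duplicate spots interleaved per feature
        flags = rng.random(2 * cfg.n_features) < cfg.missing_rate

        pos_conc = np.repeat(POSITIVE_CONTROL_CONCS, POSITIVE_CONTROL_COUNTS)
        slope = rng.normal(6.0e4, 3.0e3)
        pos = slope * pos_conc + rng.normal(0.0, 800.0, pos_conc.size)
        neg = np.minimum(np.abs(rng.normal(30.0, 15.0, NEGATIVE_CONTROL_COUNT)), 95.0)

        n_feat_spots = 2 * cfg.n_features
        n_spots = n_feat_spots + pos_conc.size + neg.size
        frame = pd.DataFrame(
            {
                "array_id": array_id,
                "spot_id": np.arange(1, n_spots + 1),
                "feature_id": np.concatenate(
                    [
                        np.repeat(feature_ids, 2),
                        [f"POS_{c}" for c in pos_conc],
                        ["NEG"] * neg.size,
                    ]
                ),
                "intensity": np.concatenate([values, np.maximum(pos, 1.0), neg]),
                "flag": np.concatenate(
                    [flags, np.zeros(pos_conc.size + neg.size, dtype=bool)]
                ),
                "control_type": np.concatenate(
                    [
                        np.repeat("none", n_feat_spots),
                        np.repeat("positive", pos_conc.size),
                        np.repeat("negative", neg.size),
                    ]
                ),
                "control_conc": np.concatenate(
                    [
                        np.full(n_feat_spots, np.nan),
                        pos_conc,
                        np.full(neg.size, np.nan),
                    ]
                ),
            }
        )
        frames.append(frame)

    spot_table = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        reactive_feature_ids=[feature_ids[i] for i in sorted(reactive_idx)],
        gamma=pd.DataFrame(gamma, index=feature_ids).T,
        delta=pd.DataFrame(delta, index=feature_ids).T,
        session=session,
        baseline=pd.Series(baseline, index=feature_ids),
    )
    return spot_table, annotation, truth


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="array_id")
    ann["run"] = ann["run"].astype(int)
    return ann
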