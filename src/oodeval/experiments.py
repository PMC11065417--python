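"""End-to-end experiment drivers for the three performance axes.

Axis 1 — classifier accuracy: score ID/OOD test sets through a sequence of
training checkpoints of one reference classifier (each tagged with its
held-out accuracy) and record AUROC per (checkpoint, method).

Axis 2 — degree of out-of-domainness: sweep the OOD displacement ``delta``
from 0 (OOD identical to ID in distribution) upward and record AUROC and
FPR95 per (delta, method, seed).

Axis 3 — detector-fitting imbalance: refit the Mahalanobis detector on
balanced / long-tailed / uniform-random class-size profiles of equal total
size and score one fixed shared test set; MSP and energy take no fitting
data, so their rows are bit-identical across profiles by construction.

Every driver is a pure function of its config; results are tidy tables
(experiment, factor_name, factor_value, method, metric, value, seed).
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier_adapter import (
    ClassifierAdapter,
    SplitSpec,
    split_dataset,
    train_reference_classifier,
)
from .evaluation import (
    accuracy_at_threshold,
    equalize_sizes,
    five_number_summary,
    roc_curve,
)
from .ood_scores import (
    METHOD_MAH,
    METHODS,
    EnergyConfig,
    fit_gaussian_model,
    score_dataset,
)
from .records import FeatureTable
from .synthetic_data import (
    BALANCED,
    UNBALANCED_EMPIRICAL,
    UNBALANCED_UNIFORM,
    ClassSizeProfile,
    FeatureSpaceSpec,
    OODShiftSpec,
    generate_id_features,
    generate_ood_features,
    make_class_size_profile,
)

_METRICS = ("auroc", "fpr95", "accuracy")


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings shared by the three experiment drivers.

    Defaults are desk-scale: a 12-class, 8-dimensional feature space with
    class means of scale 3 against unit within-class variance — separations
    comparable to a moderately good penultimate layer — and test sets of a
    few hundred samples per side.
    """

    methods: tuple[str, ...] = METHODS
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    # feature-space geometry
    n_classes: int = 12
    dim: int = 8
    mean_scale: float = 3.0
    within_var: float = 1.0
    n_per_class: int = 100
    # OOD generation
    shift_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0)
    shift_mode: str = "mean-shift"
    n_ood_test: int = 1000
    test_delta: float = 3.0
    # reference-classifier training (desk-scale schedule)
    epochs: int = 40
    learning_rate: float = 1e-2
    batch_size: int = 64
    hidden_dim: int = 16
    checkpoint_epochs: tuple[int, ...] = (1, 2, 4, 8, 16, 40)
    # imbalance experiment
    imbalance_n_total: int = 96
    imbalance_min_count: int = 2
    imbalance_n_test: int = 1500
    temperature: float = 1.0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be non-empty")
        bad = set(m.upper() for m in self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        object.__setattr__(self, "methods", tuple(m.upper() for m in self.methods))
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        if any(d < 0 for d in self.shift_grid):
            raise ValueError("shift grid must be nonnegative")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentTable:
    """Tidy result rows; ``frame`` columns are the table schema."""

    frame: pd.DataFrame

    COLUMNS = (
        "experiment",
        "factor_name",
        "factor_value",
        "method",
        "metric",
        "value",
        "seed",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.frame = self.frame[list(self.COLUMNS)].reset_index(drop=True)
        bad_metric = set(self.frame["metric"]) - set(_METRICS)
        if bad_metric:
            raise ValueError(f"unknown metrics: {sorted(bad_metric)}")
        vals = self.frame["value"].to_numpy(dtype=float)
        if len(vals) and ((vals < 0) | (vals > 1)).any():
            raise ValueError("metric values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @staticmethod
    def from_rows(rows: Iterable[dict]) -> "ExperimentTable":
        return ExperimentTable(pd.DataFrame(list(rows), columns=ExperimentTable.COLUMNS))

    @staticmethod
    def concat(tables: Iterable["ExperimentTable"]) -> "ExperimentTable":
        frames = [t.frame for t in tables]
        return ExperimentTable(pd.concat(frames, ignore_index=True))

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


# ----------------------------------------------------------------- plumbing


def _feature_spec(config: ExperimentConfig, seed: int) -> FeatureSpaceSpec:
    return FeatureSpaceSpec(
        n_classes=config.n_classes,
        dim=config.dim,
        mean_scale=config.mean_scale,
        within_cov=config.within_var,
        seed=seed,
    )


def _id_splits(config: ExperimentConfig, spec: FeatureSpaceSpec, seed: int):
    profile = make_class_size_profile(
        BALANCED, config.n_per_class * config.n_classes, config.n_classes
    )
    table = generate_id_features(spec, profile)
    return split_dataset(table, SplitSpec(seed=seed))


def _score_pair(
    id_table: FeatureTable,
    ood_table: FeatureTable,
    adapter: ClassifierAdapter,
    method: str,
    model,
    temperature: float,
):
    cfg = EnergyConfig(temperature)
    s_id = score_dataset(id_table, adapter, method, model=model, config=cfg).scores
    s_ood = score_dataset(ood_table, adapter, method, model=model, config=cfg).scores
    return s_id, s_ood


def _fit_mah(adapter: ClassifierAdapter, id2: FeatureTable):
    return fit_gaussian_model(adapter.features(id2.features), id2.label_array())


# -------------------------------------------------------------- experiments


def run_oodness_sweep(config: ExperimentConfig) -> ExperimentTable:
    """AUROC and FPR95 for every (delta, method, seed) on equalized test sets."""
    if len(config.shift_grid) < 2:
        raise ValueError("shift grid must contain at least 2 delta values")
    rows = []
    for seed in config.seeds:
        spec = _feature_spec(config, seed)
        id1, id2, id3 = _id_splits(config, spec, seed)
        trained = train_reference_classifier(
            id1,
            config.n_classes,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            seed=seed,
        )
        adapter = trained.adapter
        model = _fit_mah(adapter, id2) if METHOD_MAH in config.methods else None
        for delta in config.shift_grid:
            ood = generate_ood_features(
                spec, OODShiftSpec(delta, config.n_ood_test, config.shift_mode)
            )
            id_eq, ood_eq = equalize_sizes(id3, ood, seed=seed)
            for method in config.methods:
                s_id, s_ood = _score_pair(
                    id_eq, ood_eq, adapter, method, model, config.temperature
                )
                roc = roc_curve(s_id, s_ood)
                for metric, value in (("auroc", roc.auroc), ("fpr95", roc.fpr95)):
                    rows.append(
                        {
                            "experiment": "oodness_sweep",
                            "factor_name": "delta",
                            "factor_value": delta,
                            "method": method,
                            "metric": metric,
                            "value": value,
                            "seed": seed,
                        }
                    )
    return ExperimentTable.from_rows(rows)


def run_accuracy_sweep(config: ExperimentConfig) -> ExperimentTable:
    """AUROC per (checkpoint accuracy, method, seed) at a fixed OOD shift.

    The classifier is a small hidden-layer network so its penultimate
    features — and therefore the Mahalanobis fit — genuinely change from
    checkpoint to checkpoint.
    """
    wanted = sorted(set(config.checkpoint_epochs))
    if len(wanted) < 2:
        raise ValueError("need at least 2 checkpoint epochs")
    rows = []
    for seed in config.seeds:
        spec = _feature_spec(config, seed)
        id1, id2, id3 = _id_splits(config, spec, seed)
        trained = train_reference_classifier(
            id1,
            config.n_classes,
            epochs=max(wanted),
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            seed=seed,
            hidden_dim=config.hidden_dim,
        )
        checkpoints = [ck for ck in trained.checkpoints if ck.epoch in wanted]
        if len(checkpoints) < 2:
            raise ValueError("fewer than 2 requested checkpoints were produced")
        for ck in checkpoints:
            if not np.isfinite(ck.val_accuracy):
                raise ValueError(f"checkpoint {ck.epoch} lacks a held-out accuracy")
        ood = generate_ood_features(
            spec, OODShiftSpec(config.test_delta, config.n_ood_test, config.shift_mode)
        )
        id_eq, ood_eq = equalize_sizes(id3, ood, seed=seed)
        for ck in checkpoints:
            model = (
                _fit_mah(ck.adapter, id2) if METHOD_MAH in config.methods else None
            )
            for method in config.methods:
                s_id, s_ood = _score_pair(
                    id_eq, ood_eq, ck.adapter, method, model, config.temperature
                )
                roc = roc_curve(s_id, s_ood)
                rows.append(
                    {
                        "experiment": "accuracy_sweep",
                        "factor_name": "classifier_accuracy",
                        "factor_value": ck.val_accuracy,
                        "method": method,
                        "metric": "auroc",
                        "value": roc.auroc,
                        "seed": seed,
                    }
                )
    return ExperimentTable.from_rows(rows)


def _imbalance_profiles(
    config: ExperimentConfig, seed: int
) -> dict[str, ClassSizeProfile]:
    # long-tailed weights emulating a heavily skewed corpus (Zipf-like)
    empirical = 1.0 / (1.0 + np.arange(config.n_classes))
    common = dict(
        n_total=config.imbalance_n_total,
        n_classes=config.n_classes,
        min_count=config.imbalance_min_count,
    )
    return {
        BALANCED: make_class_size_profile(
            BALANCED, config.imbalance_n_total, config.n_classes
        ),
        UNBALANCED_EMPIRICAL: make_class_size_profile(
            UNBALANCED_EMPIRICAL, empirical_weights=empirical, seed=seed, **common
        ),
        UNBALANCED_UNIFORM: make_class_size_profile(
            UNBALANCED_UNIFORM, seed=seed, **common
        ),
    }


def run_imbalance_experiment(config: ExperimentConfig) -> ExperimentTable:
    """AUROC per (ID2 class-size profile, method, seed) on one fixed test set.

    Only the Mahalanobis detector is refit per profile (fresh ID2 draws with
    the profile's class counts, same class means, same classifier); MSP and
    energy are computed once and their rows repeated verbatim across
    profiles, making their insensitivity to fitting-set imbalance exact.
    """
    profiles_by_seed = {s: _imbalance_profiles(config, s) for s in config.seeds}
    totals = {
        p.n_total for by in profiles_by_seed.values() for p in by.values()
    }
    if len(totals) != 1:
        raise ValueError("imbalance profiles must share one n_total")
    rows = []
    for seed in config.seeds:
        spec = _feature_spec(config, seed)
        id1, _, _ = _id_splits(config, spec, seed)
        trained = train_reference_classifier(
            id1,
            config.n_classes,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            seed=seed,
        )
        adapter = trained.adapter
        # dedicated equal-sized test draws: profile contrasts are subtle, so
        # the shared test set must be large enough not to mask them
        id_eq = generate_id_features(
            spec,
            make_class_size_profile(BALANCED, config.imbalance_n_test, config.n_classes),
            stream=50,
        )
        ood_eq = generate_ood_features(
            spec,
            OODShiftSpec(config.test_delta, config.imbalance_n_test, config.shift_mode),
            stream=51,
        )

        fixed_scores = {}  # MSP/EBM computed once, reused across profiles
        for method in config.methods:
            if method != METHOD_MAH:
                fixed_scores[method] = _score_pair(
                    id_eq, ood_eq, adapter, method, None, config.temperature
                )
        for stream_offset, (kind, profile) in enumerate(
            profiles_by_seed[seed].items()
        ):
            for method in config.methods:
                if method == METHOD_MAH:
                    id2 = generate_id_features(
                        spec, profile, stream=100 + stream_offset
                    )
                    model = _fit_mah(adapter, id2)
                    s_id, s_ood = _score_pair(
                        id_eq, ood_eq, adapter, method, model, config.temperature
                    )
                else:
                    s_id, s_ood = fixed_scores[method]
                roc = roc_curve(s_id, s_ood)
                rows.append(
                    {
                        "experiment": "imbalance",
                        "factor_name": "profile",
                        "factor_value": kind,
                        "method": method,
                        "metric": "auroc",
                        "value": roc.auroc,
                        "seed": seed,
                    }
                )
    return ExperimentTable.from_rows(rows)


# ------------------------------------------------------------- full report


@dataclass
class ReportBundle:
    table: ExperimentTable
    summary: dict
    failures: dict[str, str]
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _baseline_summary(config: ExperimentConfig) -> dict:
    """Single-scenario per-method metrics at the reference shift."""
    seed = config.seeds[0]
    spec = _feature_spec(config, seed)
    id1, id2, id3 = _id_splits(config, spec, seed)
    trained = train_reference_classifier(
        id1,
        config.n_classes,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        seed=seed,
    )
    adapter = trained.adapter
    model = _fit_mah(adapter, id2) if METHOD_MAH in config.methods else None
    ood = generate_ood_features(
        spec, OODShiftSpec(config.test_delta, config.n_ood_test, config.shift_mode)
    )
    id_eq, ood_eq = equalize_sizes(id3, ood, seed=seed)
    out = {}
    for method in config.methods:
        s_id, s_ood = _score_pair(
            id_eq, ood_eq, adapter, method, model, config.temperature
        )
        roc = roc_curve(s_id, s_ood)
        out[method] = {
            "auroc": roc.auroc,
            "fpr95": roc.fpr95,
            "best_threshold": roc.best_threshold,
            "best_tpr": roc.best_tpr,
            "best_fpr": roc.best_fpr,
            "accuracy": accuracy_at_threshold(s_id, s_ood, roc.best_threshold),
            "id_summary": five_number_summary(s_id).as_dict(),
            "ood_summary": five_number_summary(s_ood).as_dict(),
        }
    return out


def run_full_report(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ReportBundle:
    """Run all three experiments plus the baseline summary; write the bundle.

    A failing experiment is logged and the others still run; the bundle's
    ``ok`` flag (and the CLI exit status) reflects any failure.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    drivers = {
        "oodness_sweep": run_oodness_sweep,
        "accuracy_sweep": run_accuracy_sweep,
        "imbalance": run_imbalance_experiment,
    }
    tables, failures = [], {}
    for name, driver in drivers.items():
        try:
            tables.append(driver(config))
        except Exception:
            failures[name] = traceback.format_exc()
    try:
        summary = _baseline_summary(config)
    except Exception:
        summary = {}
        failures["baseline_summary"] = traceback.format_exc()

    table = (
        ExperimentTable.concat(tables)
        if tables
        else ExperimentTable.from_rows([])
    )
    results_csv = out / "results.csv"
    table.write_csv(results_csv)
    summary_json = out / "summary.json"
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
    log_lines = [
        f"oodeval version: {__version__}",
        f"seeds: {list(config.seeds)}",
        f"config: {json.dumps(config.to_dict(), sort_keys=True)}",
        f"experiments completed: {sorted(set(drivers) - set(failures))}",
    ]
    for name, tb in failures.items():
        log_lines.append(f"FAILED {name}:\n{tb}")
    log_path = out / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    return ReportBundle(
        table=table,
        summary=summary,
        failures=failures,
        paths={"results": results_csv, "summary": summary_json, "log": log_path},
    )
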