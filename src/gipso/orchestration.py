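"""Experiment driver: data -> windows -> split -> swarm-tuned RNN ->
evaluation -> multi-run statistics -> attribution.

A tuning run searches the hyperparameter box by minimizing the validation
error rate (1 - accuracy) while tracking Cohen's kappa as the indicator.
Runs are repeated with distinct optimizer seeds over a fixed data split; the
run's best hyperparameters are refit on train+validation before the single
evaluation on the held-out final 20%, whose isolation until that point is
enforced by an access guard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, interpretation, metaheuristics, study_stats
from .data import (
    GeneratorConfig,
    WindowedDataset,
    chronological_split,
    concat_windows,
    generate_synthetic_series,
    make_windows,
    read_series_csv,
    write_series_csv,
)
from .metaheuristics import GipsoConfig, OptimizerConfig, optimize
from .recurrent_classifier import RNNParameters, build_model, predict, train
from .search_space import SearchSpace, decode, default_space

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "TestSetGuard",
    "tuning_objective",
    "run_experiment",
    "load_config",
]

logger = logging.getLogger(__name__)


class TestSetGuard:
    """Holds the reserved test windows and logs every access, so protocols
    can assert the test set was untouched before final evaluation."""

    __test__ = False  # not a test case despite the name

    def __init__(self, ds: WindowedDataset):
        self._ds = ds
        self.access_log: list[str] = []

    def acquire(self, reason: str) -> WindowedDataset:
        self.access_log.append(reason)
        return self._ds

    @property
    def touched(self) -> bool:
        return bool(self.access_log)

    def __len__(self) -> int:  # metadata only, not an access
        return len(self._ds)


@dataclass
class ExperimentConfig:
    """Full experiment description (loadable from YAML)."""

    data_path: str | None = None
    generator: GeneratorConfig | None = None
    lags: int = 15
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    variants: tuple[str, ...] = ("gipso", "pso")
    control: str = "gipso"
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    gipso: GipsoConfig = field(default_factory=GipsoConfig)
    space_overrides: dict | None = None
    repeats: int = 30
    base_seed: int = 0
    refit: bool = True
    attribution_coalitions: int = 64
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.data_path is None and self.generator is None:
            raise ValueError("either data_path or a generator config is required")
        if self.data_path is not None and not Path(self.data_path).exists():
            raise FileNotFoundError(self.data_path)
        if self.control not in self.variants:
            raise ValueError(f"control {self.control!r} not among variants")


@dataclass
class ExperimentResult:
    collections: dict[str, study_stats.RunCollection]
    best_models: dict[str, RNNParameters]
    best_variant: str
    guard: TestSetGuard
    output_dir: Path


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML file with nested sections
    mirroring the dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "generator" in kwargs and kwargs["generator"] is not None:
        kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
    if "optimizer" in kwargs:
        kwargs["optimizer"] = OptimizerConfig(**kwargs["optimizer"])
    if "gipso" in kwargs:
        kwargs["gipso"] = GipsoConfig(**kwargs["gipso"])
    for key in ("fractions", "variants"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return ExperimentConfig(**kwargs)


def tuning_objective(
    position: np.ndarray,
    space: SearchSpace,
    train_set: WindowedDataset,
    val_set: WindowedDataset,
    seed: int,
    lags: int = 15,
    record: list | None = None,
) -> float:
    """Decode a position, train the candidate network, and score it.

    Returns the validation error rate (the minimized objective) and appends
    (error, kappa) to ``record`` when given.  Any training failure is
    penalized with the worst possible fitness 1.0.
    """
    try:
        hp = decode(position, space)
        model = build_model(hp, lags=lags, seed=seed)
        train(model, train_set, val_set, hp, seed=seed)
        y_pred = predict(model, val_set.X)
        cm = evaluation.confusion_matrix(val_set.y, y_pred)
        error = evaluation.error_rate(cm)
        try:
            kappa = evaluation.cohen_kappa(cm)
        except ZeroDivisionError:
            kappa = float("nan")
    except Exception as exc:  # degenerate candidate: worst fitness
        logger.warning("candidate failed (%s); assigning fitness 1.0", exc)
        error, kappa = 1.0, float("nan")
    if record is not None:
        record.append((float(error), float(kappa)))
    return float(error)


def _load_windows(cfg: ExperimentConfig, outdir: Path) -> WindowedDataset:
    if cfg.data_path is not None:
        series = read_series_csv(cfg.data_path)
    else:
        series = generate_synthetic_series(cfg.generator, cfg.base_seed)
        write_series_csv(
            series, outdir / "data.csv", sidecar=vars(cfg.generator) | {"seed": cfg.base_seed}
        )
    return concat_windows([make_windows(s, cfg.lags) for s in series])


def _final_evaluation(
    hp,
    train_set: WindowedDataset,
    val_set: WindowedDataset,
    guard: TestSetGuard,
    seed: int,
    lags: int,
    refit: bool,
    reason: str,
) -> tuple[RNNParameters, evaluation.ConfusionMatrix]:
    if refit:
        fit_set = WindowedDataset(
            np.vstack([train_set.X, val_set.X]),
            np.concatenate([train_set.y, val_set.y]),
            lags,
        )
    else:
        fit_set = train_set
    model = build_model(hp, lags=lags, seed=seed)
    train(model, fit_set, val_set, hp, seed=seed)
    test_set = guard.acquire(reason)
    cm = evaluation.confusion_matrix(test_set.y, predict(model, test_set.X))
    return model, cm


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full tuning study and write all artifact tables as CSV."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows = _load_windows(cfg, outdir)
    train_set, val_set, test_set = chronological_split(windows, cfg.fractions)
    guard = TestSetGuard(test_set)
    space = default_space(cfg.space_overrides)

    collections: dict[str, study_stats.RunCollection] = {}
    best_models: dict[str, RNNParameters] = {}
    best_reports: dict[str, evaluation.ClassificationReport] = {}
    trace_rows, hp_rows = [], []

    for variant in cfg.variants:
        rc = study_stats.RunCollection(algorithm=variant)
        opt_cfg = replace(cfg.optimizer, variant=variant)
        variant_best = (np.inf, None, None)  # (objective, model, run)
        for r in range(cfg.repeats):
            run_seed = cfg.base_seed + r
            objective = lambda pos: tuning_objective(  # noqa: E731
                pos, space, train_set, val_set, seed=run_seed, lags=cfg.lags
            )
            result = optimize(
                objective, space, opt_cfg, cfg.gipso,
                rng=np.random.default_rng(run_seed),
            )
            hp = decode(result.best_position, space)
            model, cm = _final_evaluation(
                hp, train_set, val_set, guard, run_seed, cfg.lags,
                cfg.refit, f"{variant}/run{r}/final-evaluation",
            )
            rc.objectives.append(evaluation.error_rate(cm))
            rc.indicators.append(evaluation.cohen_kappa(cm))
            rc.seeds.append(run_seed)
            rc.best_hyperparameters.append(hp)
            for it, fit in enumerate(result.trace):
                trace_rows.append(
                    {"variant": variant, "run": r, "iteration": it,
                     "best_fitness": fit}
                )
            logger.info(
                "%s run %d: test error %.6f kappa %.6f (seed %d)",
                variant, r, rc.objectives[-1], rc.indicators[-1], run_seed,
            )
            if rc.objectives[-1] < variant_best[0]:
                variant_best = (rc.objectives[-1], model, r)
                best_reports[variant] = evaluation.classification_report(cm)
        collections[variant] = rc
        best_models[variant] = variant_best[1]
        best_r = variant_best[2]
        hp_best = rc.best_hyperparameters[best_r]
        hp_rows.append(
            {"method": variant, "learning_rate": hp_best.learning_rate,
             "dropout": hp_best.dropout, "epochs": hp_best.epochs,
             "layers": hp_best.num_layers,
             **{f"neurons_l{i+1}": (hp_best.neurons[i] if i < hp_best.num_layers else None)
                for i in range(3)}}
        )

    # --- artifact tables -------------------------------------------------
    pd.DataFrame(trace_rows).to_csv(outdir / "traces.csv", index=False)
    study_stats.summary_frame(list(collections.values()), "objectives").to_csv(
        outdir / "summary_objective.csv", index=False
    )
    study_stats.summary_frame(list(collections.values()), "indicators").to_csv(
        outdir / "summary_indicator.csv", index=False
    )
    pd.DataFrame(hp_rows).to_csv(outdir / "best_hyperparameters.csv", index=False)
    for variant, report in best_reports.items():
        evaluation.report_frame(report).to_csv(
            outdir / f"report_{variant}.csv", index=False
        )

    _write_stats_tables(collections, cfg, outdir)

    best_variant = min(collections, key=lambda v: min(collections[v].objectives))
    _write_attribution(
        best_models[best_variant], train_set, guard, cfg, outdir, best_variant
    )
    runs = pd.concat(
        [
            pd.DataFrame(
                {"variant": v, "run": range(cfg.repeats), "seed": rc.seeds,
                 "objective": rc.objectives, "indicator": rc.indicators}
            )
            for v, rc in collections.items()
        ],
        ignore_index=True,
    )
    runs.to_csv(outdir / "runs.csv", index=False)
    return ExperimentResult(collections, best_models, best_variant, guard, outdir)


def _write_stats_tables(
    collections: dict[str, study_stats.RunCollection],
    cfg: ExperimentConfig,
    outdir: Path,
) -> None:
    shapiro_rows, wilcoxon_rows = [], []
    control = collections[cfg.control]
    for variant, rc in collections.items():
        try:
            p_sw = study_stats.shapiro_wilk(rc.objectives)
        except ValueError:
            p_sw = float("nan")
        shapiro_rows.append({"method": variant, "shapiro_p": p_sw})
        if variant != cfg.control:
            try:
                p_w = study_stats.wilcoxon_signed_rank(
                    control.objectives, rc.objectives
                )
            except ValueError:
                p_w = float("nan")
            wilcoxon_rows.append({"method": variant, "wilcoxon_p": p_w})
    pd.DataFrame(shapiro_rows).to_csv(outdir / "shapiro.csv", index=False)
    pd.DataFrame(wilcoxon_rows).to_csv(outdir / "wilcoxon.csv", index=False)


def _write_attribution(
    model: RNNParameters,
    train_set: WindowedDataset,
    guard: TestSetGuard,
    cfg: ExperimentConfig,
    outdir: Path,
    best_variant: str,
) -> None:
    rng = np.random.default_rng(cfg.base_seed)
    n_bg = min(100, len(train_set))
    bg_idx = rng.choice(len(train_set), size=n_bg, replace=False)
    background = train_set.X[bg_idx]
    test = guard.acquire(f"{best_variant}/attribution")
    samples = test.X[: min(50, len(test))]
    summary = interpretation.feature_importance(
        model, background, samples,
        n_coalitions=cfg.attribution_coalitions, seed=cfg.base_seed,
    )
    interpretation.write_importance_csv(summary, outdir / "attribution.csv")
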