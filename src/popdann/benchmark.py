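"""The four-scenario benchmarking protocol and the experiment suites.

Four scenarios contextualize domain adaptation (all evaluated on the same
held-out target test set, except the source-matched benchmark which uses
the matched source test set):

* ``source_matched`` -- train and test on source data (the usual simulation
  benchmark; for genealogy tasks this means true trees on both sides);
* ``target_matched`` -- train and test on labeled target data (the
  hypothetical true model: a performance ceiling not achievable in
  practice, since real target labels don't exist);
* ``standard`` -- train on source, apply to target (the usual workflow under
  mis-specification);
* ``domain_adaptive`` -- train on labeled source plus unlabeled target with
  the gradient-reversal network.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .metrics import (
    MetricsReport,
    classification_report,
    regression_report,
    welch_t,
)
from .model import NetworkSpec, build_network, predict_values
from .scenarios import DatasetBundle, ScenarioPair, assemble_dataset
from .train import TrainingConfig, TrainingHistory, train_domain_adaptive, train_standard

__all__ = [
    "SCENARIOS",
    "ExperimentConfig",
    "ScenarioResult",
    "BenchmarkReport",
    "run_benchmark",
    "run_misspec_suite",
    "run_imbalance_suite",
]

SCENARIOS = ("source_matched", "target_matched", "standard", "domain_adaptive")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one benchmark run needs, fully seeded."""

    pair: ScenarioPair
    n_source: int
    n_target: int | None = None
    scenarios: tuple[str, ...] = SCENARIOS
    training: TrainingConfig = field(default_factory=TrainingConfig)
    replicate_seeds: tuple[int, ...] = (0,)
    target_sweep_fraction: float = 0.5
    source_target_ratio: float = 1.0
    splits: tuple[float, float, float] = (0.9, 0.02, 0.08)
    data_seed: int = 0
    network_width: int = 8
    feature_dim: int = 32
    max_sites: int = 480
    w_scale: float | None = None  # default: 4 * source present-day Ne

    def __post_init__(self) -> None:
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")


@dataclass
class ScenarioResult:
    scenario: str
    replicate_seed: int
    metrics: MetricsReport
    history: TrainingHistory


@dataclass
class BenchmarkReport:
    config: dict
    dataset_hash: str
    results: list[ScenarioResult]
    comparisons: dict = field(default_factory=dict)

    def metric_table(self) -> dict:
        table: dict[str, dict] = {}
        for r in self.results:
            table.setdefault(r.scenario, []).append(r.metrics.to_dict())
        return table

    def mean_metric(self, scenario: str, key: str) -> float:
        vals = [
            getattr(r.metrics, key)
            for r in self.results
            if r.scenario == scenario and getattr(r.metrics, key) is not None
        ]
        return float(np.mean(vals))

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "dataset_hash": self.dataset_hash,
                "metrics": self.metric_table(),
                "comparisons": self.comparisons,
            },
            indent=2,
            default=float,
        )


def _bundle_hash(bundle: DatasetBundle) -> str:
    h = hashlib.sha256()

    def upd(x):
        if isinstance(x, dict):
            for k in sorted(x):
                upd(x[k])
        elif isinstance(x, tuple):
            for v in x:
                upd(v)
        else:
            h.update(np.ascontiguousarray(x).tobytes())

    for part in (
        bundle.source_train,
        bundle.source_val,
        bundle.source_test,
        bundle.target_train,
        bundle.target_val,
        bundle.target_test,
    ):
        upd(part)
    return h.hexdigest()[:16]


def _network_spec(cfg: ExperimentConfig) -> NetworkSpec:
    pair = cfg.pair
    if pair.task == "rho_regression":
        input_shape = (cfg.max_sites, pair.source.n_samples)
    else:
        m = pair.source.n_samples - 1
        input_shape = (m, m, 3)
    return NetworkSpec(
        task=pair.task,
        input_shape=input_shape,
        width=cfg.network_width,
        feature_dim=cfg.feature_dim,
        grl_lambda=cfg.training.grl_lambda,
        w_scale=cfg.w_scale if cfg.w_scale is not None else 4.0 * pair.source.present_ne,
    )


def _swapped_bundle(bundle: DatasetBundle, cfg: ExperimentConfig) -> DatasetBundle:
    """Target-matched view: labeled target test data takes the source role.

    The hypothetical true model trains in-domain on target examples; the
    labeled target test set is split for training/validation and evaluation
    happens on the source test-sized tail kept held out.
    """
    Xt, yt = bundle.target_test

    def _n(X):
        return len(X["pos"]) if isinstance(X, dict) else len(X)

    def take(X, sl):
        return {k: v[sl] for k, v in X.items()} if isinstance(X, dict) else X[sl]

    N = _n(Xt)
    n_te = max(min(N // 4, _n(bundle.source_test[0]) if not isinstance(bundle.source_test[0], dict) else len(bundle.source_test[1])), 1)
    n_va = max(N // 20, 1)
    n_tr = N - n_te - n_va
    i = np.arange(N)
    return DatasetBundle(
        task=bundle.task,
        source_train=(take(Xt, i[:n_tr]), yt[:n_tr]),
        source_val=(take(Xt, i[n_tr : n_tr + n_va]), yt[n_tr : n_tr + n_va]),
        source_test=(take(Xt, i[n_tr + n_va :]), yt[n_tr + n_va :]),
        target_train=bundle.target_train,
        target_val=bundle.target_val,
        target_test=(take(Xt, i[n_tr + n_va :]), yt[n_tr + n_va :]),
        manifest=dict(bundle.manifest, view="target_matched"),
    )


def _evaluate(model, X, y, task) -> MetricsReport:
    values = predict_values(model, X)
    if task == "sweep_classification":
        return classification_report(task, y.astype(int), values)
    if task == "s_regression":
        # selection coefficients are learned and evaluated as log10(s)
        values = np.log10(values)
    return regression_report(task, y, values)


def run_benchmark(
    cfg: ExperimentConfig, bundle: DatasetBundle | None = None
) -> BenchmarkReport:
    """Simulate (or reuse) the domain pair once, train and evaluate scenarios.

    Each requested scenario is trained per replicate seed and evaluated on
    the shared target test set (source test set for ``source_matched``).
    The standard-vs-domain-adaptive comparison adds a Welch test on
    absolute errors (regression tasks).
    """
    if bundle is None:
        bundle = assemble_dataset(
            cfg.pair,
            n_source=cfg.n_source,
            n_target=cfg.n_target,
            target_sweep_fraction=cfg.target_sweep_fraction,
            source_target_ratio=cfg.source_target_ratio,
            splits=cfg.splits,
            seed=cfg.data_seed,
            max_sites=cfg.max_sites,
        )
    spec = _network_spec(cfg)
    results: list[ScenarioResult] = []
    tm_bundle = None
    for scenario in cfg.scenarios:
        for rep_seed in cfg.replicate_seeds:
            tcfg = dc_replace(cfg.training, seed=int(rep_seed))
            model = build_network(spec, seed=int(rep_seed))
            if scenario == "domain_adaptive":
                hist = train_domain_adaptive(model, bundle, tcfg)
                X_eval, y_eval = bundle.target_test
            elif scenario == "standard":
                hist = train_standard(model, bundle, tcfg)
                X_eval, y_eval = bundle.target_test
            elif scenario == "source_matched":
                hist = train_standard(model, bundle, tcfg)
                X_eval, y_eval = bundle.source_test
            else:  # target_matched
                if len(bundle.target_test[1]) == 0:
                    raise ValueError(
                        "target_matched requires labeled target test data"
                    )
                if tm_bundle is None:
                    tm_bundle = _swapped_bundle(bundle, cfg)
                hist = train_standard(model, tm_bundle, tcfg)
                X_eval, y_eval = tm_bundle.source_test
            results.append(
                ScenarioResult(
                    scenario=scenario,
                    replicate_seed=int(rep_seed),
                    metrics=_evaluate(model, X_eval, y_eval, cfg.pair.task),
                    history=hist,
                )
            )
    report = BenchmarkReport(
        config=_config_dict(cfg),
        dataset_hash=_bundle_hash(bundle),
        results=results,
    )
    _add_comparisons(report, cfg)
    return report


def _config_dict(cfg: ExperimentConfig) -> dict:
    return {
        "label": cfg.pair.label,
        "task": cfg.pair.task,
        "n_source": cfg.n_source,
        "n_target": cfg.n_target,
        "scenarios": list(cfg.scenarios),
        "replicate_seeds": list(cfg.replicate_seeds),
        "target_sweep_fraction": cfg.target_sweep_fraction,
        "source_target_ratio": cfg.source_target_ratio,
        "splits": list(cfg.splits),
        "data_seed": cfg.data_seed,
        "network_width": cfg.network_width,
        "max_sites": cfg.max_sites,
        "training": {
            "batch_size": cfg.training.batch_size,
            "grl_lambda": cfg.training.grl_lambda,
            "learning_rate": cfg.training.learning_rate,
            "max_epochs": cfg.training.max_epochs,
            "patience": cfg.training.patience,
            "domain_mix_fraction": cfg.training.domain_mix_fraction,
        },
    }


def _add_comparisons(report: BenchmarkReport, cfg: ExperimentConfig) -> None:
    if not {"standard", "domain_adaptive"} <= set(cfg.scenarios):
        return
    if cfg.pair.task == "sweep_classification":
        report.comparisons["standard_vs_domain_adaptive"] = {
            "auprc_standard": report.mean_metric("standard", "auprc"),
            "auprc_domain_adaptive": report.mean_metric("domain_adaptive", "auprc"),
        }
        return
    std = [r for r in report.results if r.scenario == "standard"]
    da = [r for r in report.results if r.scenario == "domain_adaptive"]
    abs_std = np.concatenate(
        [np.abs(r.metrics.predictions - r.metrics.truth) for r in std]
    )
    abs_da = np.concatenate(
        [np.abs(r.metrics.predictions - r.metrics.truth) for r in da]
    )
    t, df, p = welch_t(abs_std, abs_da)
    report.comparisons["standard_vs_domain_adaptive"] = {
        "mae_standard": report.mean_metric("standard", "mae"),
        "mae_domain_adaptive": report.mean_metric("domain_adaptive", "mae"),
        "welch_t_abs_error": t,
        "welch_df": df,
        "welch_p": p,
    }


def run_misspec_suite(
    cfg: ExperimentConfig, degrees: list[str]
) -> dict[str, BenchmarkReport]:
    """One benchmark per mis-specification degree preset.

    ``degrees`` draws from the presets (tree_inference_only, bottleneck_8000
    ... bottleneck_500, extreme). AUPRC/RMSE across degrees plus the
    starting domain-classifier loss per degree are what the severity
    figures tabulate.
    """
    from .scenarios import MISSPEC_PRESETS

    unknown = set(degrees) - set(MISSPEC_PRESETS)
    if unknown:
        raise ValueError(f"unknown mis-specification presets: {sorted(unknown)}")
    reports = {}
    for degree in degrees:
        pair = MISSPEC_PRESETS[degree](
            task=cfg.pair.task,
            n_samples=cfg.pair.source.n_samples,
            L=cfg.pair.source.L,
        )
        reports[degree] = run_benchmark(dc_replace(cfg, pair=pair))
    return reports


def run_imbalance_suite(
    cfg: ExperimentConfig,
    sweep_fractions: list[float] = (0.5,),
    ratios: list[float] = (1.0,),
) -> dict[tuple, BenchmarkReport]:
    """Class-imbalance and source:target-size-ratio experiments.

    Target train/val data follow each requested sweep fraction; evaluation
    always uses the balanced target test set. Ratios > 1 shrink the target
    domain relative to the source.
    """
    if any(not (0.0 <= f <= 1.0) for f in sweep_fractions):
        raise ValueError("sweep fractions must lie in [0, 1]")
    if any(r < 1.0 for r in ratios):
        raise ValueError("source:target ratios must be >= 1")
    reports = {}
    for frac in sweep_fractions:
        for ratio in ratios:
            reports[(frac, ratio)] = run_benchmark(
                dc_replace(
                    cfg,
                    target_sweep_fraction=frac,
                    source_target_ratio=ratio,
                    n_target=None,
                )
            )
    return reports
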