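"""End-to-end orchestration: clean -> normalize -> split -> feature
selection -> hyperparameter tuning -> final fit -> metric report.

Feature selection and tuning only ever see the training side of the 80/20
stratified split; normalization parameters are fitted on the training rows
and applied unchanged to the test rows.  A leakage guard asserts that no
test row also appears in the training table (rows are unique after
cleaning, so content equality identifies a leak).  One master seed drives
labelled substreams for every stage, making whole runs bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import bpo, dho, lstm, synth
from .metrics import MetricReport
from .preprocess import (
    FeatureTable,
    SplitSpec,
    clean,
    kfold_indices,
    min_max_apply,
    min_max_fit_transform,
    stratified_split,
)
from .rng import substream


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs for one run; ``preset`` fills stage budgets by scale.

    ``scale='full'`` uses the reference budgets (population 40 over 150
    iterations for feature selection, herd 30 over 50 iterations for
    tuning, 10-fold CV, 200-epoch cap); ``'desk'`` is a reduced-budget
    profile for interactive use and testing.
    """

    input_csv: str | None = None
    synth_n: int = 768
    signal: synth.SignalSpec | None = None
    scale: str = "desk"
    seed: int = 0
    train_fraction: float = 0.8
    k_folds: int = 5
    val_fraction: float = 0.15
    bpo_m: int = 10
    bpo_iters: int = 20
    bpo_C: float = 0.2
    fs_classifier: str = "logistic"
    dho_n: int = 6
    dho_iters: int = 10
    fitness_epochs: int = 30
    max_epochs: int = 100
    patience: int = 10
    outdir: str | None = None

    @classmethod
    def preset(cls, scale: str = "desk", **overrides) -> "PipelineConfig":
        if scale == "full":
            base = dict(
                scale="full", k_folds=10, bpo_m=40, bpo_iters=150,
                fs_classifier="lstm", dho_n=30, dho_iters=50,
                fitness_epochs=50, max_epochs=200,
            )
        elif scale == "desk":
            base = dict(
                scale="desk", k_folds=5, bpo_m=10, bpo_iters=20,
                fs_classifier="logistic", dho_n=6, dho_iters=10,
                fitness_epochs=30, max_epochs=100,
            )
        else:
            raise PipelineError(f"unknown scale preset {scale!r}")
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.signal is not None:
            d["signal"] = dataclasses.asdict(self.signal)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    mask: bpo.FeatureMask
    hyper: lstm.LSTMHyper
    test_report: MetricReport
    cv_reports: list
    fs_trace: list
    tune_trace: list
    train_loss: list
    val_loss: list
    leakage_overlap: int
    config: dict
    config_hash: str
    seed: int
    timestamp: float = field(default_factory=time.time)

    def to_dict(self, include_timestamp: bool = True) -> dict:
        d = {
            "mask": self.mask.to_dict(),
            "hyper": self.hyper.to_dict(),
            "test_report": self.test_report.to_dict(),
            "cv_reports": [r.to_dict() for r in self.cv_reports],
            "fs_trace": [float(x) for x in self.fs_trace],
            "tune_trace": [float(x) for x in self.tune_trace],
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "leakage_overlap": self.leakage_overlap,
            "config": self.config,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }
        if include_timestamp:
            d["timestamp"] = self.timestamp
        return d


def _seed_for(master: int, label: str) -> int:
    return int(substream(master, label).integers(2**31))


def _load_table(config: PipelineConfig) -> FeatureTable:
    if config.input_csv is not None:
        path = Path(config.input_csv)
        if not path.exists():
            raise PipelineError(f"input file not found: {path}")
        return FeatureTable.from_csv(path)
    return synth.generate(
        config.synth_n,
        signal=config.signal,
        seed=substream(config.seed, "synth"),
    )


def _prepare(config: PipelineConfig):
    """Shared front half: load, clean, split, normalize."""
    table, cleaning = clean(_load_table(config))
    train, test = stratified_split(
        table,
        SplitSpec(config.train_fraction, max(config.k_folds, 2), _seed_for(config.seed, "split")),
    )
    train_norm, norm_params = min_max_fit_transform(train)
    test_norm = min_max_apply(test, norm_params, _warn_out_of_range=False)
    overlap = len(
        {tuple(r) for r in train.values} & {tuple(r) for r in test.values}
    )
    if overlap:
        raise PipelineError(f"leakage guard fired: {overlap} rows shared between splits")
    return table, cleaning, train_norm, test_norm, norm_params, overlap


def run_bold(config: PipelineConfig) -> RunReport:
    """Execute the six-stage flow and return the consolidated report."""
    _, _, train_norm, test_norm, norm_params, overlap = _prepare(config)

    evaluator = bpo.make_cv_accuracy_evaluator(
        train_norm,
        k=config.k_folds,
        seed=_seed_for(config.seed, "folds"),
        classifier=config.fs_classifier,
    )
    mask, fs_trace = bpo.select_features(
        train_norm, evaluator, m=config.bpo_m, max_itr=config.bpo_iters,
        C=config.bpo_C, seed=_seed_for(config.seed, "bpo"),
    )

    hyper, tune_trace = dho.tune_hyperparameters(
        train_norm, mask.bits, n=config.dho_n, m_itr=config.dho_iters,
        seed=_seed_for(config.seed, "dho"), fitness_epochs=config.fitness_epochs,
        val_fraction=config.val_fraction,
    )

    # final refit on the full training split (internal early-stopping carve-out)
    masked_train = train_norm.select_attributes(mask.bits)
    masked_test = test_norm.select_attributes(mask.bits)
    fit_part, val_part = stratified_split(
        masked_train,
        SplitSpec(1.0 - config.val_fraction, 2, _seed_for(config.seed, "refit")),
    )
    params, history = lstm.train(
        fit_part, val_part, hyper,
        max_epochs=config.max_epochs, patience=config.patience,
        seed=_seed_for(config.seed, "lstm"),
    )
    labels, probs = lstm.predict(masked_test, params)
    test_report = MetricReport.from_predictions(masked_test.outcome, labels, probs)

    # per-fold CV metrics of the final configuration (reduced epoch cap)
    cv_reports = []
    folds = kfold_indices(
        masked_train, SplitSpec(config.train_fraction, config.k_folds, _seed_for(config.seed, "folds"))
    )
    for tr, va in folds:
        p_fold, _ = lstm.train(
            masked_train.take_rows(tr), masked_train.take_rows(va), hyper,
            max_epochs=config.fitness_epochs, patience=config.patience,
            seed=_seed_for(config.seed, "lstm"),
        )
        fold_labels, fold_probs = lstm.predict(masked_train.take_rows(va), p_fold)
        cv_reports.append(
            MetricReport.from_predictions(masked_train.outcome[va], fold_labels, fold_probs)
        )

    report = RunReport(
        mask=mask,
        hyper=hyper,
        test_report=test_report,
        cv_reports=cv_reports,
        fs_trace=list(map(float, fs_trace)),
        tune_trace=list(map(float, tune_trace)),
        train_loss=history.train_loss,
        val_loss=history.val_loss,
        leakage_overlap=overlap,
        config=config.to_dict(),
        config_hash=config.hash(),
        seed=config.seed,
    )
    if config.outdir is not None:
        _write_artifacts(report, params, norm_params, config)
    return report


def _write_artifacts(report: RunReport, params, norm_params, config: PipelineConfig):
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "mask.json").write_text(json.dumps(report.mask.to_dict(), indent=2))
    (out / "hyper.json").write_text(json.dumps(report.hyper.to_dict(), indent=2))
    (out / "model.json").write_text(params.to_json())
    (out / "normalization.json").write_text(norm_params.to_json())
    loss_lines = ["epoch,train_loss,val_loss"] + [
        f"{i + 1},{tr},{va}"
        for i, (tr, va) in enumerate(zip(report.train_loss, report.val_loss))
    ]
    (out / "loss.csv").write_text("\n".join(loss_lines) + "\n")


class MajorityClassBaseline:
    """Predicts the training majority class with constant probability."""

    def fit(self, X, y):
        self.p_ = float(np.mean(y))
        return self

    def predict_proba_1(self, X):
        return np.full(X.shape[0], self.p_)


class LogisticBaseline:
    def __init__(self):
        self.clf = LogisticRegression(max_iter=500)

    def fit(self, X, y):
        self.clf.fit(X, y)
        return self

    def predict_proba_1(self, X):
        return self.clf.predict_proba(X)[:, 1]


def compare_baselines(config: PipelineConfig, baselines: dict | None = None) -> dict:
    """Score pluggable baselines under the same split protocol.

    Returns {name: MetricReport}.  A baseline must expose ``fit(X, y)`` and
    ``predict_proba_1(X)``; a failing baseline is skipped with its error
    recorded under the key ``"<name>__error"``.
    """
    _, _, train_norm, test_norm, _, _ = _prepare(config)
    if baselines is None:
        baselines = {"majority": MajorityClassBaseline(), "logistic": LogisticBaseline()}
    results: dict = {}
    for name, model in baselines.items():
        try:
            model.fit(train_norm.values, train_norm.outcome)
            probs = np.asarray(model.predict_proba_1(test_norm.values), dtype=float)
            labels = (probs >= 0.5).astype(int)
            results[name] = MetricReport.from_predictions(test_norm.outcome, labels, probs)
        except Exception as exc:  # noqa: BLE001 - other baselines proceed
            results[f"{name}__error"] = str(exc)
    return results
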