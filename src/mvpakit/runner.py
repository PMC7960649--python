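"""Orchestrate a job: cross-validation loop, leakage-safe rescaling, training, scoring.

Each cross-validation iteration draws its own seed from the master seed via a
counter-based seed sequence, splits the data, fits the rescaler on the
training partition only, applies it to every partition, builds a *fresh*
model, trains it, and scores the held-out test set with winner-take-all
decisions.  The validation partition is used for per-epoch monitoring only —
never for rescaler fitting or parameter selection.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data import (
    DataSet,
    apply_rescaler,
    fit_rescaler,
    flatten_examples,
    loader_from_file,
    resolve_loader,
    split_loop_over_sa,
    split_single,
)
from .job import JobSpec, validate_job
from .models import ModelSpec, build_model, classify_wta, predict_scores, train

__all__ = [
    "AnalysisConfig",
    "IterationResult",
    "ResultsBundle",
    "run_job",
    "accuracy",
    "iteration_seed",
]


def accuracy(pred_labels, true_labels) -> float:
    """Fraction of exact label matches."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth must be equal-length and non-empty")
    return float(np.mean(pred == true))


def iteration_seed(master_seed: int, iteration: int) -> int:
    """Independent per-iteration seed stream from (master seed, counter)."""
    ss = np.random.SeedSequence([int(master_seed), int(iteration)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class AnalysisConfig:
    scheme: str = "single"
    fractions: tuple[float, float, float] = (0.8, 0.0, 0.2)
    n_iterations: int = 1
    seed: int = 0
    loop_attr: str | None = None
    loop_mode: str = "leave_group_out"
    rescale: dict | None = None
    target_attr: str = "condition"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.scheme not in ("single", "loop_over_sa"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "loop_over_sa" and not self.loop_attr:
            raise ValueError("loop_over_sa requires a loop attribute name")

    @classmethod
    def from_job(cls, job: JobSpec) -> "AnalysisConfig":
        an, da = job.analysis, job.data
        fr = an.get("fractions", [0.8, 0.0, 0.2])
        if isinstance(fr, dict):
            fr = (fr.get("train", 0.0), fr.get("val", 0.0), fr.get("test", 0.0))
        rescale = da.get("rescale")
        if isinstance(rescale, str):
            rescale = {"method": rescale}
        return cls(
            scheme=an.get("scheme", "single"),
            fractions=tuple(float(f) for f in fr),
            n_iterations=int(an.get("n_iterations", 1)),
            seed=int(an.get("seed", 0)),
            loop_attr=an.get("loop_attr"),
            loop_mode=an.get("loop_mode", "leave_group_out"),
            rescale=rescale,
            target_attr=da.get("target_attr", "condition"),
        )


@dataclass
class IterationResult:
    iteration_id: int
    test_accuracy: float
    train_accuracy: float
    val_accuracy: float | None
    loss: float | None
    scores: np.ndarray  # (n_test, K)
    true_labels: np.ndarray  # integer-coded test labels
    test_idx: np.ndarray
    start_time: float
    end_time: float
    group_value: object | None = None
    converged: bool = True


@dataclass
class ResultsBundle:
    results: list[IterationResult]
    n_classes: int
    class_labels: list
    metadata: dict = field(default_factory=dict)
    job: JobSpec | None = None
    trained_model: object = None  # last iteration's TrainedModel, for export

    @property
    def test_accuracies(self) -> np.ndarray:
        return np.array([r.test_accuracy for r in self.results])


def _load_dataset(job: JobSpec, base_dir: Path | None) -> DataSet:
    da = job.data
    path = Path(da.get("path", ""))
    if base_dir is not None and not path.is_absolute():
        candidate = base_dir / path
        if candidate.exists() or not path.exists():
            path = candidate
    params = dict(da.get("params", {}))
    if "data_var" in da:
        params["data_var"] = da["data_var"]
    if "attr_vars" in da:
        params["attr_vars"] = da["attr_vars"]
    if "loader_path" in da:
        loader = loader_from_file(da["loader_path"], da.get("loader_func", "load"))
    else:
        loader = resolve_loader(da["loader"])
    return loader(path, **params)


def _encode_labels(values: np.ndarray):
    classes, codes = np.unique(values, return_inverse=True)
    return classes, codes.astype(int)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_job(
    job: JobSpec,
    base_dir: str | Path | None = None,
    seed_override: int | None = None,
    dataset: DataSet | None = None,
) -> ResultsBundle:
    """Execute a validated job and return the collected results.

    ``dataset`` may be supplied directly (library use), bypassing the loader;
    ``base_dir`` anchors relative data paths (typically the job file's
    directory).  Outputs are *not* written here — pass the bundle to
    :func:`mvpakit.outputs.write_outputs`.
    """
    issues = [i for i in validate_job(job) if i.level == "error"]
    if issues:
        raise ValueError(
            "job failed validation: " + "; ".join(str(i) for i in issues)
        )
    cfg = AnalysisConfig.from_job(job)
    if seed_override is not None:
        cfg.seed = int(seed_override)

    with _stage("load_data"):
        ds = dataset if dataset is not None else _load_dataset(job, Path(base_dir) if base_dir else None)
        class_labels, y_all = _encode_labels(ds.attribute(cfg.target_attr))
        n_classes = len(class_labels)

    spec = ModelSpec.from_dict(job.model)
    classical = spec.backend == "classical"
    work = flatten_examples(ds) if classical else ds
    X_all = np.asarray(work.data, dtype=float)
    input_shape = X_all.shape[1:]

    with _stage("split"):
        plans = []
        if cfg.scheme == "single":
            for it in range(cfg.n_iterations):
                s = iteration_seed(cfg.seed, it)
                plans.append((it, None, split_single(ds, cfg.fractions, s, iteration_id=it)))
        else:
            per_iter = [
                split_loop_over_sa(ds, cfg.loop_attr, cfg.loop_mode, cfg.fractions,
                                   iteration_seed(cfg.seed, it))
                for it in range(cfg.n_iterations)
            ]
            n_groups = len(per_iter[0])
            # ordering: (group, iteration)
            k = 0
            for g in range(n_groups):
                for it in range(cfg.n_iterations):
                    plan = per_iter[it][g]
                    plans.append((k, plan.group_value, plan))
                    k += 1

    results: list[IterationResult] = []
    last_tm = None
    for run_id, group_value, plan in plans:
        t0 = time.time()
        with _stage("rescale"):
            if cfg.rescale:
                method = cfg.rescale["method"]
                params = {k: v for k, v in cfg.rescale.items()
                          if k not in ("method", "per_feature")}
                rp = fit_rescaler(X_all[plan.train_idx], method, params,
                                  per_feature=bool(cfg.rescale.get("per_feature", False)))
                X_train = apply_rescaler(rp, X_all[plan.train_idx])
                X_val = apply_rescaler(rp, X_all[plan.val_idx]) if len(plan.val_idx) else X_all[plan.val_idx]
                X_test = apply_rescaler(rp, X_all[plan.test_idx])
            else:
                X_train = X_all[plan.train_idx]
                X_val = X_all[plan.val_idx]
                X_test = X_all[plan.test_idx]
        y_train, y_val, y_test = (y_all[plan.train_idx], y_all[plan.val_idx],
                                  y_all[plan.test_idx])

        with _stage("train"):
            it_seed = iteration_seed(cfg.seed, 10_000 + run_id)
            if not classical:
                spec.training = {**spec.training, "seed": it_seed}
            model = build_model(spec, input_shape, n_classes)
            tm = train(model, X_train, y_train,
                       X_val if len(plan.val_idx) else None,
                       y_val if len(plan.val_idx) else None)

        with _stage("score"):
            scores = predict_scores(tm, X_test)
            test_acc = accuracy(classify_wta(scores), y_test)
            train_acc = accuracy(classify_wta(predict_scores(tm, X_train)), y_train)
            val_acc = (accuracy(classify_wta(predict_scores(tm, X_val)), y_val)
                       if len(plan.val_idx) else None)
            loss = None
            if tm.kind == "deep":
                loss, _ = tm.impl.evaluate(X_test, y_test)

        results.append(IterationResult(
            iteration_id=run_id,
            test_accuracy=test_acc,
            train_accuracy=train_acc,
            val_accuracy=val_acc,
            loss=loss,
            scores=scores,
            true_labels=y_test,
            test_idx=plan.test_idx,
            start_time=t0,
            end_time=time.time(),
            group_value=group_value,
            converged=tm.converged,
        ))
        last_tm = tm

    metadata = {
        "toolbox_version": __version__,
        "numpy_version": np.__version__,
        "platform": platform.platform(),
        "python_version": platform.python_version(),
        "master_seed": cfg.seed,
        "scheme": cfg.scheme,
        "n_iterations": cfg.n_iterations,
        "backend": spec.backend,
    }
    return ResultsBundle(results=results, n_classes=n_classes,
                         class_labels=[c.item() if hasattr(c, "item") else c
                                       for c in class_labels],
                         metadata=metadata, job=job, trained_model=last_tm)
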