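"""Write result products as TSV files plus model/job copies; summarize accuracies.

All TSVs share one dialect: UTF-8, header row, tab separator, '.' decimal,
no quoting, floats at 6 significant digits.  The token ``"all"`` expands to
every output kind except the specialized ``model`` export.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .job import write_job_copy
from .models import save_model
from .runner import ResultsBundle

__all__ = ["OutputRequest", "write_outputs", "summarize_accuracy", "ALL_KINDS"]

ALL_KINDS = (
    "test_accuracy",
    "train_accuracy",
    "val_accuracy",
    "scores",
    "labels",
    "timestamps",
    "metadata",
    "model",
    "job_copy",
)


@dataclass
class OutputRequest:
    """Which products to write, where, and under what filename prefix."""

    directory: Path
    prefix: str
    kinds: tuple[str, ...] = ("test_accuracy",)

    def __post_init__(self) -> None:
        self.directory = Path(self.directory)
        unknown = set(self.kinds) - set(ALL_KINDS)
        if unknown:
            raise ValueError(f"unknown output kind(s) {sorted(unknown)}; known: {ALL_KINDS}")

    @classmethod
    def from_section(cls, output_section: dict) -> "OutputRequest":
        kinds = output_section.get("kinds", "all")
        if kinds == "all":
            kinds = tuple(k for k in ALL_KINDS if k != "model")
        return cls(
            directory=Path(output_section.get("directory", ".")),
            prefix=output_section.get("prefix", "results"),
            kinds=tuple(kinds),
        )


def _fmt(x, exact: bool = False) -> str:
    if x is None:
        return "NA"
    if isinstance(x, (float, np.floating)):
        # accuracy/loss columns use the shortest round-trip repr so that
        # downstream summaries are bit-faithful; other floats use 6 s.f.
        return repr(float(x)) if exact else f"{float(x):.6g}"
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list], exact: bool = False) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(_fmt(v, exact) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _accuracy_rows(bundle: ResultsBundle, attr: str):
    rows = []
    for r in bundle.results:
        value = getattr(r, attr)
        if value is None:
            continue
        row = [r.iteration_id, value]
        if r.loss is not None and attr == "test_accuracy":
            row.append(r.loss)
        rows.append(row)
    return rows


def write_outputs(bundle: ResultsBundle, req: OutputRequest) -> list[Path]:
    """Write every requested product; returns the list of written paths.

    On I/O failure, the raised error message lists the files already
    completed.
    """
    req.directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    K = bundle.n_classes

    def tsv_path(kind: str) -> Path:
        return req.directory / f"{req.prefix}_{kind}.tsv"

    try:
        for kind in req.kinds:
            if kind in ("test_accuracy", "train_accuracy", "val_accuracy"):
                has_loss = kind == "test_accuracy" and any(
                    r.loss is not None for r in bundle.results
                )
                header = ["iteration", "accuracy"] + (["loss"] if has_loss else [])
                p = tsv_path(kind)
                _write_tsv(p, header, _accuracy_rows(bundle, kind), exact=True)
                written.append(p)
            elif kind == "scores":
                header = ["iteration", "example_index", "true_label"] + [
                    f"score_class_{c}" for c in range(K)
                ]
                rows = []
                for r in bundle.results:
                    for ex, yt, sc in zip(r.test_idx, r.true_labels, r.scores):
                        rows.append([r.iteration_id, int(ex), int(yt), *sc])
                p = tsv_path(kind)
                _write_tsv(p, header, rows)
                written.append(p)
            elif kind == "labels":
                header = ["iteration", "example_index", "true_label", "predicted_label"]
                rows = []
                for r in bundle.results:
                    pred = np.asarray(r.scores).argmax(axis=1)
                    for ex, yt, yp in zip(r.test_idx, r.true_labels, pred):
                        rows.append([r.iteration_id, int(ex), int(yt), int(yp)])
                p = tsv_path(kind)
                _write_tsv(p, header, rows)
                written.append(p)
            elif kind == "timestamps":
                header = ["iteration", "start_time", "end_time", "elapsed_seconds"]
                rows = [
                    [
                        r.iteration_id,
                        time.strftime("%Y-%m-%dT%H:%M:%S", time.localtime(r.start_time)),
                        time.strftime("%Y-%m-%dT%H:%M:%S", time.localtime(r.end_time)),
                        r.end_time - r.start_time,
                    ]
                    for r in bundle.results
                ]
                p = tsv_path(kind)
                _write_tsv(p, header, rows)
                written.append(p)
            elif kind == "metadata":
                header = ["key", "value"]
                rows = [[k, v] for k, v in sorted(bundle.metadata.items())]
                rows.append(["class_labels", ",".join(map(str, bundle.class_labels))])
                p = tsv_path(kind)
                _write_tsv(p, header, rows)
                written.append(p)
            elif kind == "model":
                if bundle.trained_model is None:
                    raise ValueError("no trained model available to export")
                p = req.directory / f"{req.prefix}_model.npz"
                save_model(bundle.trained_model, p)
                written.append(p)
            elif kind == "job_copy":
                if bundle.job is None:
                    raise ValueError("bundle carries no job to copy")
                p = req.directory / f"{req.prefix}_job.json"
                write_job_copy(bundle.job, p)
                written.append(p)
    except OSError as e:
        raise OSError(
            f"output failed ({e}); completed files: {[str(w) for w in written]}"
        ) from e
    return written


def summarize_accuracy(paths: list[str | Path]) -> dict[str, dict[str, float]]:
    """Per-file mean / sample sd / sem / n over the ``accuracy`` column.

    A single-row file reports sd and sem as 0 with n = 1 so downstream
    tooling can exclude it explicitly.
    """
    out: dict[str, dict[str, float]] = {}
    for path in paths:
        path = Path(path)
        lines = path.read_text(encoding="utf-8").strip().splitlines()
        if not lines:
            raise ValueError(f"malformed accuracy file (empty): {path}")
        header = lines[0].split("\t")
        if "accuracy" not in header:
            raise ValueError(f"malformed accuracy file (no 'accuracy' column): {path}")
        col = header.index("accuracy")
        try:
            values = np.array([float(ln.split("\t")[col]) for ln in lines[1:]])
        except (ValueError, IndexError) as e:
            raise ValueError(f"malformed accuracy file {path}: {e}") from e
        n = len(values)
        if n == 0:
            raise ValueError(f"accuracy file has no data rows: {path}")
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        sem = sd / np.sqrt(n) if n > 1 else 0.0
        out[str(path)] = {"mean": mean, "sd": sd, "sem": float(sem), "n": n}
    return out
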