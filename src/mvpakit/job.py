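"""Parse, validate, and round-trip the JSON job files that fully specify an analysis.

A job file has four sections — ``model``, ``data``, ``analysis``, ``output`` —
mapping onto the model backend, the dataset/loader/rescaling, the
cross-validation plan, and the requested output products.  The legal key set
of each section is defined by the packaged ``schema.json`` (this package's
documented dialect); unknown keys *inside* a section are warnings for forward
compatibility, while unknown top-level sections are hard errors.

Serialization is canonical (sorted keys, 2-space indent) so that the job copy
saved alongside results is diff-stable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .data import RESCALE_METHODS, known_loaders

__all__ = [
    "JobSpec",
    "Issue",
    "parse_job",
    "validate_job",
    "serialize_job",
    "write_job_copy",
    "load_schema",
    "load_sample_job",
    "sample_job_names",
]

SECTIONS = ("model", "data", "analysis", "output")


def load_schema() -> dict:
    """The packaged schema document defining allowed keys per section."""
    with resources.files("mvpakit").joinpath("schema.json").open("r") as f:
        return json.load(f)


@dataclass
class JobSpec:
    """Parsed four-section job configuration."""

    model: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def sections(self) -> dict[str, dict]:
        return {"model": self.model, "data": self.data,
                "analysis": self.analysis, "output": self.output}

    def to_dict(self) -> dict:
        return {k: v for k, v in self.sections().items()}


@dataclass(frozen=True)
class Issue:
    """One validation finding.  ``level`` is "error" or "warning"."""

    level: str
    section: str
    message: str

    def __str__(self) -> str:
        return f"[{self.level}] {self.section}: {self.message}"


class JobError(ValueError):
    pass


def parse_job(text: str) -> JobSpec:
    """Parse a JSON job document into a :class:`JobSpec`.

    Raises
    ------
    JobError
        On JSON syntax errors (with line/column info), a missing section
        (named), a non-object section, or an unknown top-level key.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise JobError(f"JSON syntax error at line {e.lineno}, column {e.colno}: {e.msg}") from e
    if not isinstance(doc, dict):
        raise JobError("job document must be a JSON object with four sections")
    unknown = sorted(set(doc) - set(SECTIONS))
    if unknown:
        raise JobError(f"unknown top-level key(s) {unknown}; expected sections {list(SECTIONS)}")
    missing = [s for s in SECTIONS if s not in doc]
    if missing:
        raise JobError(f"missing required section(s): {missing}")
    for s in SECTIONS:
        if not isinstance(doc[s], dict):
            raise JobError(f"section {s!r} must be a JSON object")
    return JobSpec(**{s: doc[s] for s in SECTIONS})


def _fractions_of(analysis: dict):
    fr = analysis.get("fractions")
    if fr is None:
        return None
    if isinstance(fr, dict):
        return (fr.get("train", 0.0), fr.get("val", 0.0), fr.get("test", 0.0))
    if isinstance(fr, (list, tuple)) and len(fr) == 3:
        return tuple(fr)
    return "malformed"


def validate_job(job: JobSpec, schema: dict | None = None) -> list[Issue]:
    """Semantic validation; returns a list of issues (empty = valid).

    Pure: never raises for content problems and never mutates the job.
    """
    schema = schema or load_schema()
    issues: list[Issue] = []

    def err(section, msg):
        issues.append(Issue("error", section, msg))

    def warn(section, msg):
        issues.append(Issue("warning", section, msg))

    for name, section in job.sections().items():
        allowed = set(schema["sections"][name]["keys"])
        for key in sorted(set(section) - allowed):
            warn(name, f"unknown key {key!r} (ignored)")

    # analysis
    an = job.analysis
    scheme = an.get("scheme")
    if scheme is None:
        err("analysis", "missing 'scheme'")
    elif scheme not in schema["schemes"]:
        err("analysis", f"unknown scheme {scheme!r}; known: {schema['schemes']}")
    elif scheme == "loop_over_sa" and not an.get("loop_attr"):
        err("analysis", "scheme 'loop_over_sa' requires a 'loop_attr' attribute name")
    fr = _fractions_of(an)
    if fr is None:
        err("analysis", "missing 'fractions'")
    elif fr == "malformed":
        err("analysis", "'fractions' must be [train, val, test] or {train, val, test}")
    else:
        if any(not (0 <= float(f) <= 1) for f in fr):
            err("analysis", f"fractions must lie in [0, 1]: {fr}")
        elif sum(float(f) for f in fr) > 1 + 1e-12:
            err("analysis", f"fractions exceed 1 (sum {sum(map(float, fr)):g})")
    n_it = an.get("n_iterations", 1)
    if not (isinstance(n_it, int) and n_it >= 1):
        err("analysis", f"'n_iterations' must be an integer >= 1, got {n_it!r}")

    # data
    da = job.data
    loader = da.get("loader")
    if loader is None and "loader_path" not in da:
        err("data", "missing 'loader' (or 'loader_path'/'loader_func')")
    elif loader is not None and "loader_path" not in da and loader not in known_loaders():
        err("data", f"unresolvable loader {loader!r}; known loaders: {known_loaders()}")
    rescale = da.get("rescale")
    if rescale is not None:
        method = rescale.get("method") if isinstance(rescale, dict) else rescale
        if method not in schema["rescale_methods"]:
            err("data", f"unknown rescale method {method!r}; known: {schema['rescale_methods']}")
        elif method == "percentile" and not (
            isinstance(rescale, dict) and "p" in rescale
        ):
            err("data", "percentile rescaling requires an explicit 'p' parameter")

    # model
    mo = job.model
    backend = mo.get("backend", "classical")
    if backend not in schema["backends"]:
        err("model", f"unknown backend {backend!r}; known: {schema['backends']}")
    elif backend == "classical":
        algo = mo.get("algorithm", "smlr")
        if algo not in schema["classical_algorithms"]:
            err("model", f"unknown classical algorithm {algo!r}")
    else:
        layers = mo.get("layers")
        if not layers:
            err("model", "deep backend requires a non-empty 'layers' list")
        else:
            for i, ls in enumerate(layers):
                kind = ls.get("kind") if isinstance(ls, dict) else None
                if kind not in schema["layer_kinds"]:
                    err("model", f"layer {i}: unknown kind {kind!r}")

    # output
    kinds = job.output.get("kinds", "all")
    if kinds != "all":
        if not isinstance(kinds, list):
            err("output", "'kinds' must be \"all\" or a list of kind names")
        else:
            for k in kinds:
                if k not in schema["output_kinds"]:
                    err("output", f"unknown output kind {k!r}")

    return issues


def serialize_job(job: JobSpec) -> str:
    """Canonical serialization: sorted keys, 2-space indent, trailing newline."""
    return json.dumps(job.to_dict(), sort_keys=True, indent=2) + "\n"


def write_job_copy(job: JobSpec, destination: str | Path) -> Path:
    """Save a canonical copy of the job next to its results; returns the path."""
    destination = Path(destination)
    destination.write_text(serialize_job(job), encoding="utf-8")
    return destination


# ---------------------------------------------------------------------------
# Packaged sample jobs
# ---------------------------------------------------------------------------


def sample_job_names() -> list[str]:
    root = resources.files("mvpakit").joinpath("sample_jobs")
    return sorted(p.name for p in root.iterdir() if p.name.endswith(".json"))


def load_sample_job(name: str) -> JobSpec:
    """Load one of the packaged sample jobs (e.g. ``classical_smlr.json``)."""
    path = resources.files("mvpakit").joinpath("sample_jobs", name)
    return parse_job(path.read_text(encoding="utf-8"))
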