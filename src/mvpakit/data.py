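"""Dataset container, file loaders, cross-validation splitting, and leakage-safe rescaling.

The central object is :class:`DataSet`: an N-dimensional numeric array whose
first axis indexes examples (trials), together with named per-example "sample
attributes" (condition labels, subject identity, ...).  Attributes serve as
classification targets or as grouping variables for cross-validation.

Rescaling is deliberately leakage-safe: statistics are fitted on the training
partition only (:func:`fit_rescaler`) and then applied unchanged to any
partition (:func:`apply_rescaler`).
"""

from __future__ import annotations

import importlib.util
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DataSet",
    "SplitPlan",
    "RescaleParams",
    "load_generic",
    "register_loader",
    "resolve_loader",
    "loader_from_file",
    "known_loaders",
    "flatten_examples",
    "split_single",
    "split_loop_over_sa",
    "fit_rescaler",
    "apply_rescaler",
    "RESCALE_METHODS",
]

RESCALE_METHODS = ("percentile", "standardize", "mean_center", "map_range")


@dataclass
class DataSet:
    """Examples-by-features data plus per-example sample attributes.

    Parameters
    ----------
    data : ndarray, shape (n_examples, d1[, d2, ...])
        Numeric array; axis 0 always indexes examples.
    sample_attributes : dict of str -> ndarray, each of length n_examples
        Per-example labels (categorical or numeric).
    """

    data: np.ndarray
    sample_attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 1:
            raise ValueError("data must have at least one axis (examples)")
        n = self.data.shape[0]
        attrs = {}
        for name, vec in self.sample_attributes.items():
            vec = np.asarray(vec)
            if vec.ndim != 1 or len(vec) != n:
                raise ValueError(
                    f"sample attribute {name!r} has length "
                    f"{vec.shape[0] if vec.ndim else 0}, expected {n}"
                )
            attrs[name] = vec
        self.sample_attributes = attrs
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            bad = int(np.size(self.data) - np.count_nonzero(np.isfinite(self.data)))
            raise ValueError(f"data contains {bad} non-finite (NaN/Inf) values")

    @property
    def n_examples(self) -> int:
        return self.data.shape[0]

    def attribute(self, name: str) -> np.ndarray:
        try:
            return self.sample_attributes[name]
        except KeyError:
            raise KeyError(
                f"unknown sample attribute {name!r}; "
                f"available: {sorted(self.sample_attributes)}"
            ) from None


@dataclass
class SplitPlan:
    """Disjoint train/validation/test example indices for one CV iteration."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    iteration_id: int = 0
    group_value: object | None = None

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=np.intp)
        self.val_idx = np.asarray(self.val_idx, dtype=np.intp)
        self.test_idx = np.asarray(self.test_idx, dtype=np.intp)
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("train/val/test index sets are not pairwise disjoint")


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

_LOADER_REGISTRY: dict[str, Callable] = {}


def register_loader(name: str, func: Callable) -> None:
    """Register a loader callable ``func(path, **params) -> DataSet`` under ``name``."""
    if not callable(func):
        raise TypeError("loader must be callable")
    _LOADER_REGISTRY[name] = func


def resolve_loader(name: str) -> Callable:
    try:
        return _LOADER_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown loader {name!r}; known loaders: {sorted(_LOADER_REGISTRY)}"
        ) from None


def known_loaders() -> list[str]:
    return sorted(_LOADER_REGISTRY)


def loader_from_file(path: str | Path, func_name: str) -> Callable:
    """Import a loader function from an arbitrary user-specified .py file."""
    path = Path(path)
    spec = importlib.util.spec_from_file_location(path.stem, path)
    if spec is None or spec.loader is None:
        raise ImportError(f"cannot import loader module from {path}")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    try:
        return getattr(mod, func_name)
    except AttributeError:
        raise ImportError(f"{path} defines no function {func_name!r}") from None


def _read_npz(path: Path) -> dict[str, np.ndarray]:
    with np.load(path, allow_pickle=False) as npz:
        return {k: npz[k] for k in npz.files}


def _read_mat(path: Path) -> dict[str, np.ndarray]:
    import h5py
    import scipy.io

    if not h5py.is_hdf5(path):
        raw = scipy.io.loadmat(path, squeeze_me=True, chars_as_strings=True)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    else:
        # HDF5-backed .mat dialect (v7.3)

        out: dict[str, np.ndarray] = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                node = f[k]
                if not isinstance(node, h5py.Dataset):
                    continue
                arr = node[()]
                if "MATLAB_class" in node.attrs and arr.ndim >= 2:
                    arr = arr.T  # MATLAB stores column-major
                out[k] = np.squeeze(arr) if arr.ndim == 2 and 1 in arr.shape else arr
        return out


def load_generic(
    path: str | Path, data_var: str, attr_vars: Sequence[str]
) -> DataSet:
    """Load a DataSet from an .npz or .mat container file.

    The container must hold one array variable of data examples (``data_var``)
    plus one or more sample-attribute vectors (``attr_vars``).

    Raises
    ------
    KeyError
        If a named variable is missing from the container.
    ValueError
        If an attribute vector's length does not match the number of examples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such data file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".npz":
        variables = _read_npz(path)
    elif suffix == ".mat":
        variables = _read_mat(path)
    elif suffix == ".npy":
        raise ValueError(
            "a bare .npy holds a single array and cannot carry sample "
            "attributes; save an .npz with named data and attribute arrays"
        )
    else:
        raise ValueError(f"unsupported container format: {path.suffix!r}")

    missing = [v for v in [data_var, *attr_vars] if v not in variables]
    if missing:
        raise KeyError(
            f"variable(s) {missing} not found in {path.name}; "
            f"available: {sorted(variables)}"
        )
    attrs = {name: np.atleast_1d(variables[name]) for name in attr_vars}
    return DataSet(data=variables[data_var], sample_attributes=attrs)


def _load_generic_npz(path, data_var="data", attr_vars=("condition",), **_):
    return load_generic(path, data_var, attr_vars)


def _load_generic_mat(path, data_var="data", attr_vars=("condition",), **_):
    return load_generic(path, data_var, attr_vars)


register_loader("generic", _load_generic_npz)
register_loader("generic_npy", _load_generic_npz)
register_loader("generic_mat", _load_generic_mat)


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------


def flatten_examples(ds: DataSet) -> DataSet:
    """Collapse feature axes into one: (n, d1, d2, ...) -> (n, d1*d2*...).

    Element order is row-major over the feature axes; sample attributes are
    carried over unchanged.  Already-2-D input is returned as an equal copy.
    """
    flat = ds.data.reshape(ds.n_examples, -1)
    return DataSet(data=flat, sample_attributes=dict(ds.sample_attributes))


# ---------------------------------------------------------------------------
# Cross-validation splitting
# ---------------------------------------------------------------------------


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def _check_fractions(fractions: Sequence[float]) -> tuple[float, float, float]:
    tr, va, te = (float(f) for f in fractions)
    for f in (tr, va, te):
        if f < 0 or f > 1:
            raise ValueError(f"fractions must lie in [0, 1], got {fractions}")
    if tr + va + te > 1 + 1e-12:
        raise ValueError(f"fractions sum to {tr + va + te:g} > 1")
    return tr, va, te


def _partition(indices: np.ndarray, fractions, rng: np.random.Generator):
    """Shuffle ``indices`` and carve test/val/train counts off the front.

    Test and validation sizes are round-half-to-even of n*fraction; the
    training set takes the remainder of the selected examples (all remaining
    examples when the fractions sum to 1).
    """
    tr, va, te = _check_fractions(fractions)
    n = len(indices)
    n_test = _round_half_even(n * te)
    n_val = _round_half_even(n * va)
    if tr + va + te >= 1 - 1e-12:
        n_train = n - n_test - n_val
    else:
        n_train = min(_round_half_even(n * tr), n - n_test - n_val)
    for count, frac, label in (
        (n_train, tr, "train"),
        (n_val, va, "validation"),
        (n_test, te, "test"),
    ):
        if frac > 0 and count == 0:
            raise ValueError(
                f"{label} partition is empty (n={n}, fraction={frac}); "
                "too few examples for the requested split"
            )
    perm = rng.permutation(indices)
    test = perm[:n_test]
    val = perm[n_test : n_test + n_val]
    train = perm[n_test + n_val : n_test + n_val + n_train]
    return np.sort(train), np.sort(val), np.sort(test)


def split_single(
    ds: DataSet, fractions: Sequence[float], seed: int, iteration_id: int = 0
) -> SplitPlan:
    """The "single" scheme: one pool, randomly divided by (train, val, test) fractions."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    train, val, test = _partition(np.arange(ds.n_examples), fractions, rng)
    return SplitPlan(train, val, test, iteration_id=iteration_id)


def split_loop_over_sa(
    ds: DataSet,
    attr: str,
    mode: str = "leave_group_out",
    fractions: Sequence[float] = (0.8, 0.0, 0.2),
    seed: int = 0,
) -> list[SplitPlan]:
    """The "loop_over_sa" scheme: one split plan per value of a grouping attribute.

    Parameters
    ----------
    mode : {"leave_group_out", "within_group"}
        ``leave_group_out``: the iterated value's examples form the test set
        and all other examples form the training pool (a validation set is
        carved from that pool by the validation fraction) — the
        leave-one-subject-out pattern.  ``within_group``: each plan splits
        only that value's examples by the given fractions.
    """
    values = ds.attribute(attr)
    distinct = np.unique(values)
    if len(distinct) < 2:
        raise ValueError(
            f"loop_over_sa needs >= 2 distinct values of {attr!r}, "
            f"found {len(distinct)}"
        )
    if mode not in ("leave_group_out", "within_group"):
        raise ValueError(f"unknown loop_over_sa mode {mode!r}")
    plans = []
    for g, value in enumerate(distinct):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), g]))
        member = np.flatnonzero(values == value)
        if mode == "within_group":
            train, val, test = _partition(member, fractions, rng)
        else:
            others = np.flatnonzero(values != value)
            _, va_frac, _ = _check_fractions(fractions)
            n_val = _round_half_even(len(others) * va_frac)
            perm = rng.permutation(others)
            val = np.sort(perm[:n_val])
            train = np.sort(perm[n_val:])
            test = member
        plans.append(
            SplitPlan(train, val, test, iteration_id=g, group_value=value.item()
                      if hasattr(value, "item") else value)
        )
    return plans


# ---------------------------------------------------------------------------
# Rescaling
# ---------------------------------------------------------------------------


@dataclass
class RescaleParams:
    """Frozen rescaling statistics, fitted on the training partition only."""

    method: str
    stats: dict[str, np.ndarray | float]
    params: dict[str, float] = field(default_factory=dict)


def fit_rescaler(
    train_data: np.ndarray,
    method: str,
    params: dict | None = None,
    per_feature: bool = False,
) -> RescaleParams:
    """Fit rescaling statistics on the training partition.

    Methods
    -------
    - ``percentile``: divide by the value at percentile ``p`` of the training
      data (``p`` must be given explicitly in ``params``).
    - ``standardize``: subtract the training mean, divide by the training
      sample standard deviation (n-1 denominator).
    - ``mean_center``: subtract the training mean.
    - ``map_range``: affinely map training min -> ``lo`` and max -> ``hi``
      (defaults 0 and 1); values outside the training range are not clipped.

    Statistics are computed globally over all elements of the training
    partition by default; ``per_feature=True`` computes them along axis 0.
    """
    params = dict(params or {})
    x = np.asarray(train_data, dtype=float)
    axis = 0 if per_feature else None
    if method == "percentile":
        if "p" not in params:
            raise ValueError("percentile rescaling requires an explicit 'p' parameter")
        q = np.percentile(x, params["p"], axis=axis)  # linear interpolation
        if np.any(q == 0):
            raise ValueError("degenerate scale: training percentile value is 0")
        stats = {"q": q}
    elif method == "standardize":
        sd = np.std(x, axis=axis, ddof=1)
        if np.any(sd == 0):
            raise ValueError("degenerate scale: training standard deviation is 0")
        stats = {"mean": np.mean(x, axis=axis), "sd": sd}
    elif method == "mean_center":
        stats = {"mean": np.mean(x, axis=axis)}
    elif method == "map_range":
        lo_v, hi_v = np.min(x, axis=axis), np.max(x, axis=axis)
        if np.any(hi_v == lo_v):
            raise ValueError("degenerate scale: training min equals max")
        params.setdefault("lo", 0.0)
        params.setdefault("hi", 1.0)
        stats = {"min": lo_v, "max": hi_v}
    else:
        raise ValueError(
            f"unknown rescale method {method!r}; choose from {RESCALE_METHODS}"
        )
    return RescaleParams(method=method, stats=stats, params=params)


def apply_rescaler(rp: RescaleParams, data: np.ndarray) -> np.ndarray:
    """Apply fitted rescaling statistics to any partition."""
    x = np.asarray(data, dtype=float)
    s = rp.stats
    if rp.method == "percentile":
        return x / s["q"]
    if rp.method == "standardize":
        return (x - s["mean"]) / s["sd"]
    if rp.method == "mean_center":
        return x - s["mean"]
    if rp.method == "map_range":
        lo, hi = rp.params["lo"], rp.params["hi"]
        return lo + (x - s["min"]) * (hi - lo) / (s["max"] - s["min"])
    raise ValueError(f"unknown rescale method {rp.method!r}")
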