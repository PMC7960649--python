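"""Synthetic fMRI-like benchmark datasets with hierarchical condition structure.

Each condition (class) has a canonical feature pattern.  A square number of
trials per condition is organized as m = sqrt(T) first-level "variations" on
the canonical pattern, each spawning m second-level "sub-variations"; every
trial's pre-mix signal is one sub-variation.  To make classification harder,
each trial is finally blended with one randomly chosen sub-variation from
every other condition.  The intent is to mimic data where a condition has a
small number of true pattern variants (e.g., different face genders within a
"faces" condition) plus trial-to-trial exemplar/measurement variation —
without striving for biological realism (no hemodynamics, spatial smoothness,
or autocorrelated noise).

A pure-noise control generator produces data whose labels carry no
information, for verifying that the full pipeline decodes at chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import DataSet

__all__ = [
    "BenchmarkConfig",
    "generate_benchmark",
    "generate_pure_noise",
    "benchmark_sweep_config",
]


@dataclass
class BenchmarkConfig:
    """Parameters of one hierarchical benchmark dataset.

    Parameters
    ----------
    n_features : int
        Feature (e.g., voxel) count.
    trials_per_condition : int
        Must be a perfect square T; the generator builds sqrt(T) variation
        groups of sqrt(T) sub-variations each.
    n_conditions : int
        Number of classes (default 3).
    noise_blend_1 : float in [0, 1]
        Noise proportion when deriving variations from the canonical signal.
    noise_blend_2 : float in [0, 1]
        Noise proportion when deriving sub-variations from a variation.
    cross_blend : float in [0, 0.5)
        Blend weight given to each *other* condition's signal in a trial;
        the total cross weight (n_conditions - 1) * cross_blend must be < 1.
    """

    n_features: int
    trials_per_condition: int
    n_conditions: int = 3
    noise_blend_1: float = 0.5
    noise_blend_2: float = 0.5
    cross_blend: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        m = math.isqrt(self.trials_per_condition)
        if m * m != self.trials_per_condition or m == 0:
            raise ValueError(
                f"trials_per_condition must be a positive perfect square, "
                f"got {self.trials_per_condition}"
            )
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        for name in ("noise_blend_1", "noise_blend_2"):
            a = getattr(self, name)
            if not 0 <= a <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {a}")
        if not 0 <= self.cross_blend < 0.5:
            raise ValueError(f"cross_blend must lie in [0, 0.5), got {self.cross_blend}")
        if (self.n_conditions - 1) * self.cross_blend >= 1:
            raise ValueError(
                "total cross-condition blend weight "
                f"(n_conditions-1)*cross_blend = "
                f"{(self.n_conditions - 1) * self.cross_blend:g} must be < 1"
            )

    @property
    def n_variations(self) -> int:
        return math.isqrt(self.trials_per_condition)

    def to_dict(self) -> dict:
        return asdict(self)


def generate_benchmark(cfg: BenchmarkConfig) -> DataSet:
    """Generate one hierarchical benchmark dataset.

    For each condition c a canonical signal ``s_c ~ N(0, I)`` is drawn.
    Variations are ``v = (1 - a1) * s_c + a1 * eps`` with fresh standard
    normal noise per variation; sub-variations are
    ``w = (1 - a2) * v + a2 * eps'``.  Each trial's final pattern is::

        (1 - (K - 1) * b) * w  +  b * sum over other conditions of a
                                   randomly chosen sub-variation

    Trials are emitted condition-major, then variation-major.  Sample
    attributes: ``condition``, ``variation_group``, ``subvariation``.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed)]))
    K, F, T, m = cfg.n_conditions, cfg.n_features, cfg.trials_per_condition, cfg.n_variations
    a1, a2, b = cfg.noise_blend_1, cfg.noise_blend_2, cfg.cross_blend

    # sub[c, i, j] = sub-variation j of variation i of condition c
    sub = np.empty((K, m, m, F))
    for c in range(K):
        canonical = rng.standard_normal(F)
        variations = (1 - a1) * canonical + a1 * rng.standard_normal((m, F))
        sub[c] = (1 - a2) * variations[:, None, :] + a2 * rng.standard_normal((m, m, F))

    own_weight = 1 - (K - 1) * b
    data = np.empty((K * T, F))
    condition = np.repeat(np.arange(K), T)
    variation_group = np.tile(np.repeat(np.arange(m), m), K)
    subvariation = np.tile(np.arange(m), K * m)
    flat_sub = sub.reshape(K, T, F)
    for c in range(K):
        trials = own_weight * flat_sub[c]
        for other in range(K):
            if other == c:
                continue
            pick = rng.integers(0, T, size=T)
            trials = trials + b * flat_sub[other, pick]
        data[c * T : (c + 1) * T] = trials

    return DataSet(
        data=data,
        sample_attributes={
            "condition": condition,
            "variation_group": variation_group,
            "subvariation": subvariation,
        },
    )


def generate_pure_noise(
    n_features: int, n_examples: int, n_conditions: int = 3, seed: int = 0
) -> DataSet:
    """I.i.d. standard-normal data with labels independent of the data.

    By construction the condition labels carry zero mutual information with
    the feature values, so any sound classifier should score at chance
    (1/n_conditions) on held-out examples.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    data = rng.standard_normal((n_examples, n_features))
    condition = np.arange(n_examples) % n_conditions  # independent of data
    return DataSet(data=data, sample_attributes={"condition": condition})


def benchmark_sweep_config(seed: int = 0) -> list[BenchmarkConfig]:
    """The full benchmark grid: feature counts 200..25600 (doubling) crossed
    with trials/condition 100..10000 (squares 10^2, 20^2, ..., 100^2),
    ordered by (features, trials)."""
    feature_counts = [200 * 2**k for k in range(8)]
    trial_counts = [(10 * k) ** 2 for k in range(1, 11)]
    return [
        BenchmarkConfig(n_features=f, trials_per_condition=t, seed=seed)
        for f in feature_counts
        for t in trial_counts
    ]
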