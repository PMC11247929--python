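"""Hierarchical bootstrap and permutation inference.

Neural data are nested: trials within neurons within animals.  Treating
neurons as independent samples understates between-animal variability and
makes pooled tests anti-conservative.  The hierarchical bootstrap
resamples the nesting instead: each replicate draws animals with
replacement, then units within each drawn animal with replacement (then
trials for three-level data), computes the group statistic, and the
difference distribution over replicates yields the confidence interval
and a two-sided sign-crossing p-value.

The permutation test here is the shared utility behind the shuffle nulls
used for activity-speed and pairwise correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "HierarchicalSample",
    "BootstrapResult",
    "hierarchical_bootstrap",
    "permutation_test",
]


@dataclass
class HierarchicalSample:
    """Nested values: animal -> array of unit values, or for three-level
    data animal -> dict unit -> array of trial values."""

    groups: dict

    def __post_init__(self):
        if not self.groups:
            raise InvalidArgumentError("need >= 1 animal")
        self.three_level = any(isinstance(v, dict) for v in self.groups.values())
        for animal, units in self.groups.items():
            if self.three_level:
                if not units:
                    raise InvalidArgumentError(f"animal {animal} has no units")
                for u, trials in units.items():
                    if len(np.atleast_1d(trials)) == 0:
                        raise InvalidArgumentError(
                            f"unit {u} of animal {animal} has no trials")
            elif len(np.atleast_1d(units)) == 0:
                raise InvalidArgumentError(f"animal {animal} has no units")

    @property
    def n_animals(self) -> int:
        return len(self.groups)


def _n_draws(n_animals: int) -> int:
    """Animals drawn per replicate.

    n-1 (not n) draws with replacement make the replicate-to-replicate
    variance of the animal-level mean an unbiased estimate of the true
    sampling variance (the n-out-of-n bootstrap understates it by
    (n-1)/n, which is severe for the ~5 animals typical here).
    """
    return max(1, n_animals - 1)


def _resample_once(sample: HierarchicalSample, statistic,
                   rng: np.random.Generator) -> float:
    animals = list(sample.groups)
    chosen = rng.choice(len(animals), size=_n_draws(len(animals)), replace=True)
    values = []
    for idx in chosen:
        units = sample.groups[animals[idx]]
        if sample.three_level:
            unit_keys = list(units)
            for uidx in rng.choice(len(unit_keys), size=len(unit_keys),
                                   replace=True):
                trials = np.atleast_1d(units[unit_keys[uidx]])
                values.append(statistic(rng.choice(trials, size=trials.size,
                                                   replace=True)))
        else:
            arr = np.atleast_1d(np.asarray(units, dtype=float))
            values.extend(arr[rng.integers(0, arr.size, size=arr.size)])
    return float(statistic(np.asarray(values, dtype=float)))


def _resample_two_level_vectorized(sample: HierarchicalSample, n_boot: int,
                                   rng: np.random.Generator) -> np.ndarray:
    """Bootstrap distribution of the mean for two-level data (fast path)."""
    arrays = [np.atleast_1d(np.asarray(v, dtype=float))
              for v in sample.groups.values()]
    n_a = len(arrays)
    m = _n_draws(n_a)
    animal_idx = rng.integers(0, n_a, size=(n_boot, m))
    sizes = np.array([a.size for a in arrays])
    # Per replicate: sum of per-animal resampled sums / total count.
    sums = np.empty((n_boot, m))
    counts = sizes[animal_idx]
    for col in range(m):
        for a in range(n_a):
            mask = animal_idx[:, col] == a
            if not mask.any():
                continue
            arr = arrays[a]
            draws = rng.integers(0, arr.size, size=(int(mask.sum()), arr.size))
            sums[mask, col] = arr[draws].sum(axis=1)
    return sums.sum(axis=1) / counts.sum(axis=1)


@dataclass
class BootstrapResult:
    """Difference-of-groups bootstrap summary."""

    statistic_distribution: np.ndarray
    point_estimate: float
    ci: tuple[float, float]
    p_two_sided: float
    ci_level: float = 0.95


def _point_estimate(sample: HierarchicalSample, statistic) -> float:
    values = []
    for units in sample.groups.values():
        if sample.three_level:
            values.extend(statistic(np.atleast_1d(t)) for t in units.values())
        else:
            values.extend(np.atleast_1d(np.asarray(units, dtype=float)))
    return float(statistic(np.asarray(values, dtype=float)))


def hierarchical_bootstrap(a: HierarchicalSample, b: HierarchicalSample,
                           statistic=np.mean, n_boot: int = 10_000,
                           seed: int = 0, ci_level: float = 0.95
                           ) -> BootstrapResult:
    """Bootstrap the difference ``statistic(a) - statistic(b)``.

    Each replicate draws n_animals - 1 animals with replacement (see
    :func:`_n_draws`), then units within each chosen animal (then trials
    for three-level data).  The two-sided
    p-value is ``2 * min(P(diff > 0), P(diff < 0))`` with add-one
    smoothing, so it is never exactly zero.  A single-animal sample
    triggers a warning (between-animal uncertainty unidentifiable) and
    falls back to unit-level resampling for that group.
    """
    for name, s in (("a", a), ("b", b)):
        if s.n_animals == 1:
            warnings.warn(
                f"sample {name} has a single animal; animal-level "
                "uncertainty is unidentifiable, resampling units only"
            )
    rng = np.random.default_rng(seed)
    fast = (statistic is np.mean and not a.three_level and not b.three_level)
    if fast:
        dist_a = _resample_two_level_vectorized(a, n_boot, rng)
        dist_b = _resample_two_level_vectorized(b, n_boot, rng)
        dist = dist_a - dist_b
    else:
        dist = np.array([
            _resample_once(a, statistic, rng) - _resample_once(b, statistic, rng)
            for _ in range(n_boot)
        ])
    alpha = 1.0 - ci_level
    ci = (float(np.quantile(dist, alpha / 2)),
          float(np.quantile(dist, 1 - alpha / 2)))
    n_pos = int(np.sum(dist > 0))
    n_neg = int(np.sum(dist < 0))
    p = 2.0 * (1 + min(n_pos, n_neg)) / (1 + n_boot)
    return BootstrapResult(
        statistic_distribution=dist,
        point_estimate=_point_estimate(a, statistic) - _point_estimate(b, statistic),
        ci=ci,
        p_two_sided=float(min(p, 1.0)),
        ci_level=ci_level,
    )


def permutation_test(x, y, statistic=None, n_perm: int = 1000,
                     seed: int = 0) -> float:
    """Two-sample permutation p-value for ``statistic(x, y)``.

    Default statistic is the difference of means.  p = (1 +
    #{|stat_perm| >= |stat_obs|}) / (1 + n_perm).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("empty input")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    if statistic is None:
        statistic = lambda u, v: np.mean(u) - np.mean(v)  # noqa: E731
    rng = np.random.default_rng(seed)
    obs = abs(statistic(x, y))
    pooled = np.concatenate([x, y])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(statistic(perm[: x.size], perm[x.size:])) >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)
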