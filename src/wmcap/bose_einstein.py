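"""Bose-Einstein occupancy distribution.

The model: ``r`` indistinguishable units ("balls") are allocated uniformly at
random over the weak compositions of ``r`` into ``n`` distinguishable cells
("boxes").  The random variable of interest is the number ``x`` of occupied
cells.  In the working-memory application the boxes are the distinct features
of a compound stimulus and the balls are units of attentional capacity, so
``x`` is the number of features detected on a trial.

The pmf is

    p(x) = C(n, n-x) * C(r-1, x-1) / C(n+r-1, r),    1 <= x <= min(n, r)

with mean ``n*r / (n+r-1)``.  Every quantity here is backed by an exhaustive
enumeration oracle (:func:`enumerate_oracle`) usable for small ``n+r``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb, exp, lgamma

import numpy as np

__all__ = [
    "BoseEinsteinSpec",
    "OccupancyDistribution",
    "be_pmf",
    "be_distribution",
    "be_mean",
    "be_sample",
    "enumerate_oracle",
]

_ENUM_GUARD = 10**6


@dataclass(frozen=True)
class BoseEinsteinSpec:
    """Parameters of one occupancy model: ``n_boxes`` cells, ``r_balls`` units."""

    n_boxes: int
    r_balls: int

    def __post_init__(self) -> None:
        for name in ("n_boxes", "r_balls"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")

    @property
    def support(self) -> range:
        """Attainable occupancy counts: 1 .. min(n, r)."""
        return range(1, min(self.n_boxes, self.r_balls) + 1)


@dataclass(frozen=True)
class OccupancyDistribution:
    """Full distribution of the number of occupied boxes for one spec."""

    spec: BoseEinsteinSpec
    support: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        total = float(np.sum(self.probabilities))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.probabilities):
            raise ValueError("negative probability")
        if 0 in self.support:
            raise ValueError("support must exclude x = 0")

    def pmf(self, x: int) -> float:
        try:
            return self.probabilities[self.support.index(x)]
        except ValueError:
            return 0.0

    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))


def _log_binom(a: int, b: int) -> float:
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def be_pmf(spec: BoseEinsteinSpec, x: int) -> float:
    """Probability that exactly ``x`` boxes are occupied.

    Returns 0.0 outside the support [1, min(n, r)]; x = 0 is a valid query
    (observed data can contain zero-correct trials) but never a positive-
    probability outcome under the model.
    """
    if not isinstance(x, (int, np.integer)) or isinstance(x, bool):
        raise TypeError(f"x must be an integer, got {x!r}")
    if x < 0:
        raise ValueError(f"x must be >= 0, got {x}")
    n, r = spec.n_boxes, spec.r_balls
    if x < 1 or x > min(n, r):
        return 0.0
    # log-space binomials: safe for n + r - 1 well beyond the ~90 used here
    log_p = _log_binom(n, n - x) + _log_binom(r - 1, x - 1) - _log_binom(n + r - 1, r)
    return exp(log_p)


@lru_cache(maxsize=4096)
def _distribution_cached(n: int, r: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    spec = BoseEinsteinSpec(n, r)
    support = tuple(spec.support)
    probs = tuple(be_pmf(spec, x) for x in support)
    return support, probs


def be_distribution(spec: BoseEinsteinSpec) -> OccupancyDistribution:
    """Full occupancy distribution over the support [1, min(n, r)]."""
    support, probs = _distribution_cached(spec.n_boxes, spec.r_balls)
    return OccupancyDistribution(spec=spec, support=support, probabilities=probs)


def be_mean(spec: BoseEinsteinSpec) -> float:
    """Expected number of occupied boxes, ``n*r / (n+r-1)``.

    The closed form equals the pmf summation sum(x * p(x)); the identity is
    exercised against the summation in the test suite.
    """
    n, r = spec.n_boxes, spec.r_balls
    return n * r / (n + r - 1)


def be_sample(
    spec: BoseEinsteinSpec,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw occupancy counts by sampling compositions uniformly.

    A weak composition of r into n parts corresponds to a choice of n-1 "bar"
    positions among n+r-1 slots (stars and bars); sampling that subset
    uniformly yields the uniform distribution over compositions that defines
    the model.  Sequential independent ball-dropping would instead give
    multinomial occupancy and is deliberately not used.

    Returns a scalar int when ``size`` is None, else an int array of shape
    ``(size,)``.
    """
    n, r = spec.n_boxes, spec.r_balls
    scalar = size is None
    count = 1 if scalar else int(size)
    if count < 0:
        raise ValueError("size must be non-negative")
    if n == 1:
        out = np.ones(count, dtype=np.int64)
        return int(out[0]) if scalar else out
    m = n + r - 1
    # uniform (n-1)-subset per draw via argpartition of iid uniforms
    u = rng.random((count, m))
    bars = np.sort(np.argpartition(u, n - 2, axis=1)[:, : n - 1], axis=1)
    edges = np.concatenate(
        [
            np.full((count, 1), -1, dtype=np.int64),
            bars,
            np.full((count, 1), m, dtype=np.int64),
        ],
        axis=1,
    )
    part_sizes = np.diff(edges, axis=1) - 1
    occupied = np.count_nonzero(part_sizes, axis=1).astype(np.int64)
    return int(occupied[0]) if scalar else occupied


def enumerate_oracle(spec: BoseEinsteinSpec) -> OccupancyDistribution:
    """Exact distribution by listing every composition (small problems only).

    Independent of :func:`be_pmf`: walks all C(n+r-1, n-1) bar placements,
    counts occupied boxes in each, and normalises.  Refuses when the number
    of compositions exceeds 10**6.
    """
    n, r = spec.n_boxes, spec.r_balls
    n_comp = comb(n + r - 1, r)
    if n_comp > _ENUM_GUARD:
        raise ValueError(
            f"enumeration guard exceeded: C({n + r - 1}, {r}) = {n_comp} > {_ENUM_GUARD}"
        )
    m = n + r - 1
    counts: dict[int, int] = {}
    if n == 1:
        counts[1] = 1
    else:
        for bars in combinations(range(m), n - 1):
            edges = (-1,) + bars + (m,)
            occupied = sum(
                1 for i in range(n) if edges[i + 1] - edges[i] - 1 > 0
            )
            counts[occupied] = counts.get(occupied, 0) + 1
    support = tuple(sorted(counts))
    probs = tuple(counts[x] / n_comp for x in support)
    return OccupancyDistribution(spec=spec, support=support, probabilities=probs)
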