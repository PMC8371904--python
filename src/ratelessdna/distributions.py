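"""Degree distributions and the deterministic random number generator.

A fountain code draws, for every encoded packet, a *degree* d (how many
source chunks are XORed together) from a degree distribution over 1..N.
This module provides the two Soliton distributions introduced by Luby for
the LT code, the fixed table used by the Raptor code, and user-supplied
custom distributions, together with the generator that makes every draw
reproducible from a 32-bit seed.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "DeterministicRng",
    "DegreeDistribution",
    "ideal_soliton",
    "robust_soliton",
    "custom_distribution",
    "raptor_degree_lookup",
    "raptor_distribution",
    "sample_degree",
    "RAPTOR_DEGREE_TABLE",
]


class DeterministicRng:
    """32-bit xorshift generator with a scrambled seed.

    Every random choice in the framework (degree draws, chunk selection,
    auxiliary-block assignment, channel erasures) derives from this fixed
    generator so that a packet is bit-reproducible from its seed across
    platforms and implementations.  The xorshift constants are Marsaglia's
    (13, 17, 5) triple.

    The raw seed is passed through a murmur3-style avalanche finalizer
    before becoming the state.  This is essential, not cosmetic: packet
    seeds are often sequential (seed sweeps) or themselves xorshift
    outputs, and raw xorshift states from nearby seeds walk overlapping
    orbits, which would make "independent" packets select nearly identical
    chunk sets and stall the decoder's rank growth.  A scrambled seed of 0
    is remapped to a fixed nonzero constant (0 is the xorshift fixed
    point).
    """

    __slots__ = ("state",)

    _ZERO_SEED = 0x9E3779B9  # golden-ratio constant; any nonzero word works

    @staticmethod
    def _mix(x: int) -> int:
        # murmur3 fmix32
        x &= 0xFFFFFFFF
        x ^= x >> 16
        x = (x * 0x85EBCA6B) & 0xFFFFFFFF
        x ^= x >> 13
        x = (x * 0xC2B2AE35) & 0xFFFFFFFF
        x ^= x >> 16
        return x

    def __init__(self, seed: int) -> None:
        if seed < 0:
            raise ParameterError("seed must be non-negative")
        self.state = self._mix(seed)
        if self.state == 0:
            self.state = self._ZERO_SEED

    def next_u32(self) -> int:
        x = self.state
        x ^= (x << 13) & 0xFFFFFFFF
        x ^= x >> 17
        x ^= (x << 5) & 0xFFFFFFFF
        self.state = x
        return x

    def random(self) -> float:
        """Uniform float in [0, 1)."""
        return self.next_u32() / 4294967296.0

    def below(self, n: int) -> int:
        """Unbiased uniform integer in [0, n) via rejection sampling."""
        if n <= 0:
            raise ParameterError("below() requires n >= 1")
        limit = (1 << 32) - ((1 << 32) % n)
        while True:
            v = self.next_u32()
            if v < limit:
                return v % n


# Fixed Raptor degree table: (exclusive upper threshold, degree).  A uniform
# value v in [0, 2^20) maps to the degree of the first threshold above v.
RAPTOR_DEGREE_TABLE: tuple[tuple[int, int], ...] = (
    (10241, 1),
    (491582, 2),
    (712794, 3),
    (831695, 4),
    (948446, 10),
    (1032189, 11),
    (1 << 20, 40),
)

_RAPTOR_THRESHOLDS = [t for t, _ in RAPTOR_DEGREE_TABLE]
_RAPTOR_DEGREES = [d for _, d in RAPTOR_DEGREE_TABLE]


@dataclass(frozen=True)
class DegreeDistribution:
    """Probability mass over packet degrees 1..N.

    ``pmf[k-1]`` is the probability of degree k.  ``kind`` records how the
    distribution was built; ``K``/``delta`` are only set for the robust
    Soliton variant.
    """

    kind: str
    N: int
    pmf: np.ndarray
    K: int | None = None
    delta: float | None = None
    _cdf: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        if pmf.ndim != 1 or pmf.shape[0] != self.N or self.N < 1:
            raise ParameterError("pmf must have one entry per degree 1..N")
        if np.any(pmf < 0):
            raise ParameterError("pmf entries must be non-negative")
        if abs(float(pmf.sum()) - 1.0) > 1e-12:
            raise ParameterError("pmf must sum to 1 within 1e-12")
        object.__setattr__(self, "pmf", pmf)
        object.__setattr__(self, "_cdf", np.cumsum(pmf))

    def pmf_at(self, degree: int) -> float:
        """Probability of a given degree (0 outside 1..N)."""
        if 1 <= degree <= self.N:
            return float(self.pmf[degree - 1])
        return 0.0


def ideal_soliton(N: int) -> DegreeDistribution:
    """Ideal Soliton distribution over degrees 1..N.

    rho(1) = 1/N and rho(k) = 1/(k(k-1)) for k >= 2; the sum telescopes to
    exactly 1.  The mode sits at degree 2 with rho(2) = 0.5 for every
    N >= 2.  Mathematically ideal in expectation but fragile in practice,
    which motivates the robust variant below.
    """
    if N < 1:
        raise ParameterError("ideal_soliton requires N >= 1")
    pmf = np.empty(N)
    pmf[0] = 1.0 / N
    for k in range(2, N + 1):
        pmf[k - 1] = 1.0 / (k * (k - 1))
    return DegreeDistribution(kind="ideal_soliton", N=N, pmf=pmf)


def _robust_tau(N: int, K: int, delta: float) -> np.ndarray:
    """Unnormalized robust-Soliton spike terms tau(1..N), R = N/K."""
    R = N / K
    tau = np.zeros(N)
    for i in range(1, K):
        tau[i - 1] = 1.0 / (i * K)
    tau[K - 1] = math.log(R / delta) / K
    return tau


def robust_soliton(N: int, K: int, delta: float) -> DegreeDistribution:
    """Robust Soliton distribution.

    Adds Luby's spike terms tau(i) to the ideal distribution rho(i) and
    renormalizes: mu(i) = (rho(i) + tau(i)) / sum_j (rho(j) + tau(j)).
    ``K`` (with K < N) places an additional probability peak, and ``delta``
    is the acceptable decoding-failure probability; tau(i) = 0 for i > K.
    """
    if not (1 <= K < N):
        raise ParameterError("robust_soliton requires 1 <= K < N")
    if not (0.0 < delta < 1.0):
        raise ParameterError("robust_soliton requires delta in (0, 1)")
    rho = ideal_soliton(N).pmf
    tau = _robust_tau(N, K, delta)
    unnorm = rho + tau
    pmf = unnorm / unnorm.sum()
    return DegreeDistribution(kind="robust_soliton", N=N, pmf=pmf, K=K, delta=delta)


def custom_distribution(pmf) -> DegreeDistribution:
    """Wrap a user-supplied probability vector (degree k at index k-1)."""
    pmf = np.asarray(pmf, dtype=float)
    return DegreeDistribution(kind="custom", N=pmf.shape[0], pmf=pmf)


def raptor_degree_lookup(v: int) -> int:
    """Fixed (parameter-free) Raptor degree table.

    Maps a uniform value v in [0, 2^20) onto the degree set
    {1, 2, 3, 4, 10, 11, 40} by a piecewise-constant threshold lookup.
    Monotone non-decreasing in v.
    """
    if not (0 <= v < (1 << 20)):
        raise ParameterError("raptor lookup value must lie in [0, 2^20)")
    return _RAPTOR_DEGREES[bisect.bisect_right(_RAPTOR_THRESHOLDS, v)]


def raptor_distribution() -> DegreeDistribution:
    """The Raptor degree table expressed as an explicit pmf over 1..40."""
    pmf = np.zeros(40)
    lo = 0
    for hi, d in RAPTOR_DEGREE_TABLE:
        pmf[d - 1] += (hi - lo) / float(1 << 20)
        lo = hi
    return DegreeDistribution(kind="raptor_fixed", N=40, pmf=pmf)


def sample_degree(dist: DegreeDistribution, rng: DeterministicRng) -> int:
    """Draw one degree from ``dist`` using ``rng``.

    Inverse-CDF sampling in ascending degree order; for the fixed Raptor
    table the draw goes through :func:`raptor_degree_lookup` applied to a
    uniform integer in [0, 2^20), matching the table's native form.
    """
    if dist.kind == "raptor_fixed":
        return raptor_degree_lookup(rng.below(1 << 20))
    u = rng.random()
    idx = int(np.searchsorted(dist._cdf, u, side="right"))
    if idx >= dist.N:  # guard against u landing beyond cdf[-1] by rounding
        idx = dist.N - 1
    return idx + 1
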