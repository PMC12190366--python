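"""Buffered random-draw helpers for the trial-by-trial hot path.

A full 30-minute simulated session touches tens of thousands of random draws
one at a time; pulling them from pre-filled numpy buffers keeps the virtual
clock loop fast while remaining a pure function of the seed.
"""

from __future__ import annotations

import numpy as np

_BUFFER = 4096


class RandomPool:
    """Deterministic single-draw interface over a buffered numpy Generator."""

    __slots__ = ("_rng", "_uniform", "_normal", "_iu", "_in")

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._uniform = np.empty(0)
        self._normal = np.empty(0)
        self._iu = 0
        self._in = 0

    @property
    def generator(self) -> np.random.Generator:
        return self._rng

    def uniform(self) -> float:
        """One U(0, 1) draw."""
        if self._iu >= self._uniform.shape[0]:
            self._uniform = self._rng.random(_BUFFER)
            self._iu = 0
        u = self._uniform[self._iu]
        self._iu += 1
        return float(u)

    def normal(self) -> float:
        """One N(0, 1) draw."""
        if self._in >= self._normal.shape[0]:
            self._normal = self._rng.standard_normal(_BUFFER)
            self._in = 0
        z = self._normal[self._in]
        self._in += 1
        return float(z)

    def randint(self, n: int) -> int:
        """One uniform integer in [0, n)."""
        return min(int(self.uniform() * n), n - 1)

    def choice_excluding(self, n: int, excluded: int) -> int:
        """Uniform integer in [0, n) excluding ``excluded``."""
        k = self.randint(n - 1)
        return k if k < excluded else k + 1

    def bernoulli(self, p: float) -> bool:
        return self.uniform() < p


def pool_from_seed(seed) -> RandomPool:
    return RandomPool(np.random.default_rng(seed))
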