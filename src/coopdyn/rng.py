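"""Random-number plumbing.

The engine draws randomness only through the three primitives of
:class:`RngStream` — uniforms on [0, 1), bounded integers, and Poisson
counts — so a simulation can be driven either by a seeded generator
(:class:`SeededRng`) or, in tests, by a fully scripted stream
(:class:`ScriptedRng`) whose every draw is queued in advance.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .exceptions import ScriptExhaustedError

__all__ = ["RngStream", "SeededRng", "ScriptedRng"]


class RngStream:
    """Abstract source of randomness for the engine.

    Contract: identical streams (same seed or same script) drive
    bit-identical simulations at the level of recorded observables.
    """

    def uniform(self, size=None):
        raise NotImplementedError

    def integers(self, low, high, size=None):
        """Integers in ``[low, high)``."""
        raise NotImplementedError

    def poisson(self, lam):
        """Poisson counts, one per element of ``lam``."""
        raise NotImplementedError


class SeededRng(RngStream):
    """numpy PCG64-backed stream; the production RNG."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._g = np.random.default_rng(self.seed)

    def uniform(self, size=None):
        return self._g.random(size)

    def integers(self, low, high, size=None):
        return self._g.integers(low, high, size=size)

    def poisson(self, lam):
        return self._g.poisson(lam)


class ScriptedRng(RngStream):
    """A stream that replays queued draws, for hand-computable tests.

    Each primitive consumes from its own queue, in call order.  Raises
    :class:`ScriptExhaustedError` when over-consumed and never recycles,
    so a fixture that scripts too few draws fails loudly.
    """

    def __init__(self, uniforms=(), integers=(), poissons=()):
        self._uniforms = deque(float(u) for u in uniforms)
        self._integers = deque(int(i) for i in integers)
        self._poissons = deque(int(p) for p in poissons)

    def _take(self, queue, n, what):
        if len(queue) < n:
            raise ScriptExhaustedError(
                f"scripted {what} queue exhausted: needed {n}, had {len(queue)}"
            )
        return [queue.popleft() for _ in range(n)]

    def uniform(self, size=None):
        if size is None:
            return self._take(self._uniforms, 1, "uniform")[0]
        return np.array(self._take(self._uniforms, int(size), "uniform"))

    def integers(self, low, high, size=None):
        n = 1 if size is None else int(size)
        vals = self._take(self._integers, n, "integer")
        for v in vals:
            if not low <= v < high:
                raise ValueError(f"scripted integer {v} outside [{low}, {high})")
        if size is None:
            return vals[0]
        return np.array(vals, dtype=np.int64)

    def poisson(self, lam):
        lam = np.asarray(lam)
        if lam.ndim == 0:
            return self._take(self._poissons, 1, "poisson")[0]
        return np.array(self._take(self._poissons, lam.size, "poisson"), dtype=np.int64)

    @property
    def exhausted(self) -> bool:
        """True when every queue has been fully consumed."""
        return not (self._uniforms or self._integers or self._poissons)
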