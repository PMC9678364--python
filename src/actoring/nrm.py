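"""Next Reaction Method (NRM) event queue.

Exact stochastic simulation in the Gibson-Bruck formulation: every channel
carries an absolute tentative firing time; when a channel's propensity
changes from a_old to a_new at time t, its unfired time is rescaled as

    t_new = t + (a_old / a_new) * (t_old - t)

which preserves statistical exactness while consuming one uniform variate
per channel lifetime. The fired channel (and channels activated from zero
propensity) draw a fresh exponential.

The priority queue is a binary heap with lazy invalidation, which is simple
and fast enough at the channel counts this package uses (10^2-10^4).
"""

from __future__ import annotations

import heapq
import math

import numpy as np

INF = math.inf


class ChemicallyFrozen(Exception):
    """All channels have zero propensity; no further event can fire."""


class NRMQueue:
    """Indexed event queue mapping channel ids to tentative firing times."""

    def __init__(self, rng: np.random.Generator, time: float = 0.0):
        self.rng = rng
        self.time = float(time)
        self._a: dict = {}          # id -> propensity
        self._t: dict = {}          # id -> tentative firing time
        self._heap: list = []       # (t, seq, id); stale entries skipped
        self._seq = 0

    # ------------------------------------------------------------------
    def _push(self, cid, t):
        self._t[cid] = t
        if t < INF:
            heapq.heappush(self._heap, (t, self._seq, cid))
            self._seq += 1

    def add(self, cid, propensity: float) -> None:
        """Register a channel and draw its first firing time."""
        if propensity < 0:
            raise ValueError(f"negative propensity for channel {cid!r}")
        if cid in self._a:
            raise KeyError(f"channel {cid!r} already registered")
        self._a[cid] = propensity
        t = self.time + self.rng.exponential(1.0 / propensity) if propensity > 0 else INF
        self._push(cid, t)

    def remove(self, cid) -> None:
        self._a.pop(cid)
        self._t.pop(cid)

    def __contains__(self, cid) -> bool:
        return cid in self._a

    def propensity(self, cid) -> float:
        return self._a[cid]

    def firing_time(self, cid) -> float:
        return self._t[cid]

    def update(self, cid, propensity: float) -> None:
        """Change a channel's propensity, rescaling its pending time."""
        if propensity < 0:
            raise ValueError(f"negative propensity for channel {cid!r}")
        a_old = self._a[cid]
        if propensity == a_old:
            return
        t_old = self._t[cid]
        self._a[cid] = propensity
        if propensity == 0:
            self._t[cid] = INF
            return
        if a_old == 0 or t_old == INF:
            t_new = self.time + self.rng.exponential(1.0 / propensity)
        else:
            t_new = self.time + (a_old / propensity) * (t_old - self.time)
        self._push(cid, t_new)

    def redraw(self, cid) -> None:
        """Draw a fresh firing time for a channel (used after it fires)."""
        a = self._a[cid]
        t = self.time + self.rng.exponential(1.0 / a) if a > 0 else INF
        self._push(cid, t)

    # ------------------------------------------------------------------
    def peek(self):
        """(time, id) of the next event without firing it."""
        while self._heap:
            t, _, cid = self._heap[0]
            if cid in self._a and self._t[cid] == t and t < INF:
                return t, cid
            heapq.heappop(self._heap)
        raise ChemicallyFrozen("all channels have infinite firing time")

    def pop(self):
        """Advance to and return (time, id) of the next event.

        The caller is responsible for mutating state, updating dependent
        propensities via :meth:`update`, and calling :meth:`redraw` on the
        fired channel.
        """
        t, cid = self.peek()
        heapq.heappop(self._heap)
        if t < self.time:
            raise RuntimeError("event queue time went backwards")
        self.time = t
        self._t[cid] = INF
        return t, cid

    def has_finite_event(self) -> bool:
        try:
            self.peek()
            return True
        except ChemicallyFrozen:
            return False
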