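"""Counter-based random streams for common-random-number simulation.

Every stochastic decision in the simulation is keyed by
``(master seed, event code, year index, individual id)`` and hashed to a
uniform in [0, 1) with a splitmix64-style finalizer.  Because a draw is a
pure function of its key — not of how many draws happened before it — two
scenario arms that share a master seed receive *identical* randomness for
identical decisions, and diverge only where the scenarios themselves
differ.  This is the common-random-numbers contract the scenario
comparison relies on.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
from scipy.special import ndtri

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_C_EVENT = _U64(0xD1342543DE82EF95)
_C_YEAR = _U64(0xAF251AF3B0F025B5)


class Event(IntEnum):
    """Stable event codes; each one owns an independent random stream."""

    AGE_SEX = 1
    BMI_SDS = 2
    SBP_Z = 3
    HT_DRUG = 4
    DIABETES_PREVALENT = 5
    DIABETES_INCIDENT = 6
    ALBUMINURIA_INIT = 7
    ALBUMINURIA_ONSET = 8
    ALBUMINURIA_PROGRESSION = 9
    GFR_INIT = 10
    GFR_LOSS_FACTOR = 11
    TEST_1 = 12
    TEST_2 = 13
    ADHERENCE = 14
    DEATH = 15


def _mix(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer; uint64 arithmetic wraps intentionally
    x = (x ^ (x >> _U64(30))) * _MIX1
    x = (x ^ (x >> _U64(27))) * _MIX2
    return x ^ (x >> _U64(31))


class CRNStream:
    """A seeded stream of per-individual, per-event, per-year draws.

    Parameters
    ----------
    seed
        Master seed (non-negative integer below 2**63).
    stream
        Sub-stream label; independent stream families (e.g. the main
        cohort vs. the renal-profile cohort) use different labels.
    """

    def __init__(self, seed: int, stream: int = 0):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = int(seed)
        self.stream = int(stream)
        with np.errstate(over="ignore"):
            base = np.array([seed], dtype=np.uint64)
            base = _mix(base * _GOLDEN + _U64(stream) * _C_EVENT)
        self._base = base[0]

    def spawn(self, stream: int) -> "CRNStream":
        """Derive an independent stream family from the same master seed."""
        return CRNStream(self.seed, self.stream * 1000003 + 1 + stream)

    def uniform(self, event: Event, year: int, ids: np.ndarray) -> np.ndarray:
        """Uniform(0, 1) draws keyed by (event, year, individual id)."""
        with np.errstate(over="ignore"):
            x = ids.astype(np.uint64) * _GOLDEN
            x += self._base
            x += _U64(int(event)) * _C_EVENT
            x += _U64(int(year)) * _C_YEAR
            h = _mix(x)
        # 53 significant bits -> uniform strictly inside [0, 1)
        return (h >> _U64(11)).astype(np.float64) * (2.0**-53)

    def normal(self, event: Event, year: int, ids: np.ndarray) -> np.ndarray:
        """Standard-normal draws via the inverse CDF of :meth:`uniform`."""
        u = self.uniform(event, year, ids)
        # keep ndtri away from the exact endpoints
        return ndtri(np.clip(u, 1e-12, 1.0 - 1e-12))
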