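"""Right-continuous step functions on [0, inf).

Used for Kaplan-Meier survivor curves and Breslow cumulative hazards.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous step function.

    Parameters
    ----------
    knots
        Strictly increasing jump locations.
    values
        Function value on ``[knots[i], knots[i+1])`` (i.e. *after* the jump
        at ``knots[i]``).
    initial
        Function value on ``[0, knots[0])``.
    """

    knots: np.ndarray
    values: np.ndarray
    initial: float = 1.0

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.ndim != 1 or values.shape != knots.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    def _table(self) -> np.ndarray:
        return np.concatenate(([self.initial], self.values))

    def __call__(self, t):
        """Value at ``t`` (right-continuous: includes the jump at ``t``)."""
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float), side="right")
        out = self._table()[idx]
        return float(out) if np.isscalar(t) else out

    def eval_left(self, t):
        """Left limit, the value just before ``t``."""
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float), side="left")
        out = self._table()[idx]
        return float(out) if np.isscalar(t) else out

    def quantile_crossing(self, level: float) -> float:
        """First time the function drops to <= ``level`` (inf if never).

        For a survivor function, ``quantile_crossing(0.5)`` is the median.
        """
        below = np.nonzero(self.values <= level)[0]
        if self.initial <= level:
            return 0.0
        if below.size == 0:
            return float("inf")
        return float(self.knots[below[0]])

    def is_nonincreasing(self) -> bool:
        table = self._table()
        return bool(np.all(np.diff(table) <= 1e-12))

    def is_nondecreasing(self) -> bool:
        table = self._table()
        return bool(np.all(np.diff(table) >= -1e-12))
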