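"""Analytic potential surfaces over low-dimensional configuration vectors.

A :class:`PotentialSurface` packages an energy evaluator (kcal/mol as a
function of a configuration vector), its gradient (analytic where available,
central finite differences otherwise) and the dimension.  These surfaces
stand in for the expensive electronic-structure energies a production
workflow would evaluate, and are what the chain-of-states search, Hessian
analysis and umbrella sampling operate on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["PotentialSurface"]


@dataclass
class PotentialSurface:
    evaluator: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray] | None = None
    dimension: int = 1
    fd_step: float = 1.0e-6

    def energy(self, x) -> float:
        return float(self.evaluator(np.atleast_1d(np.asarray(x, dtype=float))))

    def grad(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.gradient is not None:
            return np.asarray(self.gradient(x), dtype=float)
        g = np.empty_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += self.fd_step
            xm[i] -= self.fd_step
            g[i] = (self.evaluator(xp) - self.evaluator(xm)) / (2.0 * self.fd_step)
        return g
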