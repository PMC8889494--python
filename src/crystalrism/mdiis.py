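"""Modified direct inversion of the iterative subspace (MDIIS).

Accelerates the self-consistent RISM cycle: coefficients a_i minimize
|sum_i a_i r_i|^2 subject to sum a_i = 1 (bordered least-squares system),
and the next guess is sum_i a_i (x_i + damping * r_i).

Classic control flow: the history is a FIFO of the last ``n_vectors``
iterates; when the current residual exceeds 10x the best residual seen, the
history is discarded and iteration restarts from the best iterate with a
reduced plain step.  A singular least-squares system (e.g. duplicate
entries) likewise triggers a restart instead of a crash.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MDIISConfig", "MDIIS", "mdiis_update"]


@dataclass
class MDIISConfig:
    n_vectors: int = 5
    damping: float = 0.7
    tolerance: float = 1e-6
    max_iterations: int = 10000
    restart_factor: float = 10.0

    def __post_init__(self):
        if self.n_vectors < 1:
            raise ValueError("n_vectors must be >= 1")
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


class MDIIS:
    """Stateful accelerator operating on flattened solution vectors."""

    def __init__(self, config: MDIISConfig):
        self.config = config
        self.solutions: list[np.ndarray] = []
        self.residuals: list[np.ndarray] = []
        self.restarts = 0
        self._best = np.inf
        self._best_x = None
        self._best_r = None

    def reset(self):
        self.solutions.clear()
        self.residuals.clear()

    def _restart(self, step_scale: float) -> np.ndarray:
        self.reset()
        self.restarts += 1
        return self._best_x + step_scale * self.config.damping * self._best_r

    def step(self, x: np.ndarray, residual: np.ndarray) -> np.ndarray:
        """Record (x, residual) and return the next guess."""
        x = np.asarray(x, float).ravel()
        residual = np.asarray(residual, float).ravel()
        cfg = self.config

        rnorm = float(np.sqrt(np.mean(residual * residual)))
        if rnorm < self._best:
            self._best = rnorm
            self._best_x = x.copy()
            self._best_r = residual.copy()
        elif rnorm > cfg.restart_factor * self._best and len(self.solutions):
            # extrapolation overshot: drop the subspace, back off to the
            # best iterate with a conservative plain step
            return self._restart(0.2)

        self.solutions.append(x)
        self.residuals.append(residual)
        if len(self.solutions) > cfg.n_vectors:
            self.solutions.pop(0)
            self.residuals.pop(0)

        m = len(self.solutions)
        if m == 1:
            return x + cfg.damping * residual

        R = np.stack(self.residuals)
        A = np.zeros((m + 1, m + 1))
        A[:m, :m] = R @ R.T
        A[:m, m] = -1.0
        A[m, :m] = -1.0
        b = np.zeros(m + 1)
        b[m] = -1.0
        try:
            coef = np.linalg.solve(A, b)[:m]
        except np.linalg.LinAlgError:
            return self._restart(1.0)
        X = np.stack(self.solutions)
        return coef @ (X + cfg.damping * R)


def mdiis_update(solutions, residuals, config: MDIISConfig) -> np.ndarray:
    """One-shot functional form: next guess from explicit histories."""
    acc = MDIIS(config)
    out = None
    for x, r in zip(solutions, residuals):
        out = acc.step(x, r)
    return out
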