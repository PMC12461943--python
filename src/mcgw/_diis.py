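"""Direct inversion in the iterative subspace (Pulay extrapolation)."""

from __future__ import annotations

import numpy as np


class DIIS:
    """Accelerate a fixed-point iteration on a flat parameter vector.

    Error vectors are successive differences of the iterates.  The normal
    equations are solved with a pseudo-inverse so near-linear-dependence in
    the subspace degrades gracefully to plain iteration.
    """

    def __init__(self, max_size: int = 12, enabled: bool = True):
        self.max_size = int(max_size)
        self.enabled = enabled
        self._vectors: list[np.ndarray] = []
        self._errors: list[np.ndarray] = []
        self._last: np.ndarray | None = None

    def update(self, vector: np.ndarray) -> np.ndarray:
        vector = np.asarray(vector, dtype=float).ravel()
        if not self.enabled:
            return vector
        if self._last is None:
            self._last = vector.copy()
            return vector
        self._vectors.append(vector.copy())
        self._errors.append(vector - self._last)
        self._vectors = self._vectors[-self.max_size:]
        self._errors = self._errors[-self.max_size:]
        self._last = vector.copy()
        if len(self._vectors) < 2:
            return vector
        k = len(self._errors)
        b = np.empty((k + 1, k + 1))
        b[:k, :k] = np.array(
            [[e1 @ e2 for e2 in self._errors] for e1 in self._errors]
        )
        b[k, :] = -1.0
        b[:, k] = -1.0
        b[k, k] = 0.0
        rhs = np.zeros(k + 1)
        rhs[k] = -1.0
        try:
            coef = np.linalg.lstsq(b, rhs, rcond=1e-14)[0][:k]
        except np.linalg.LinAlgError:  # pragma: no cover
            return vector
        if not np.all(np.isfinite(coef)):  # pragma: no cover
            return vector
        mixed = np.tensordot(coef, np.array(self._vectors), axes=1)
        self._last = mixed.copy()
        return mixed
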