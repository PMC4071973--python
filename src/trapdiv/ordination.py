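"""Principal coordinates analysis (classical metric MDS) of strain distances.

Given an n x n distance matrix D, PCoA double-centers the squared distances
(Gower centering), B = -1/2 J D^2 J with J = I - 11'/n, and eigendecomposes
the symmetric B. Coordinates on axis i are the unit eigenvector scaled by
sqrt(lambda_i); axes are ordered by descending eigenvalue, and per-axis
variance shares are taken over the positive eigenvalues only. Jaccard
distances are not guaranteed Euclidean-embeddable, so negative eigenvalues
can occur; they are reported and flagged, never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from trapdiv.errors import ValidationError
from trapdiv.similarity import DistanceMatrix

#: eigenvalues within this of zero are numerical noise, not signal
_EIG_TOL = 1e-9


@dataclass
class PCoAResult:
    """Eigenvalues, strain coordinates and variance shares of a PCoA.

    ``eigenvalues`` holds all n eigenvalues, descending. ``coordinates`` has
    one column per retained axis (the ``n_axes`` requested); axes whose
    eigenvalue is not positive carry zero coordinates.  ``pct_variance`` is
    per retained axis, as a percentage of the positive-eigenvalue total.
    """

    strain_ids: list[str]
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    pct_variance: np.ndarray
    negative_eigenvalue_flag: bool

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=self.strain_ids,
            columns=[f"axis{i + 1}" for i in range(self.n_axes)],
        )

    def write_coordinates_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="strain")

    def write_variance_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "axis": [f"axis{i + 1}" for i in range(self.n_axes)],
                "eigenvalue": self.eigenvalues[: self.n_axes],
                "pct_variance": self.pct_variance,
            }
        ).to_csv(path, index=False)


def pcoa(d: DistanceMatrix, n_axes: int = 3) -> PCoAResult:
    """Principal coordinates analysis of a distance matrix.

    ``n_axes`` must satisfy ``1 <= n_axes <= n - 1``. Eigenvector signs are
    fixed by making the largest-magnitude loading of each axis positive.
    """
    vals = np.asarray(d.values, dtype=float)
    n = d.n
    if vals.shape != (n, n) or not np.allclose(vals, vals.T):
        raise ValidationError("distance matrix must be square and symmetric")
    if not 1 <= n_axes <= n - 1:
        raise ValidationError(f"n_axes must be in [1, {n - 1}], got {n_axes}")

    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (vals**2) @ j
    b = (b + b.T) / 2.0  # symmetrize against round-off
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    coords = np.zeros((n, n_axes))
    for i in range(n_axes):
        lam = eigvals[i]
        if lam > _EIG_TOL:
            axis = eigvecs[:, i] * np.sqrt(lam)
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            coords[:, i] = axis

    positive = eigvals[eigvals > _EIG_TOL]
    total = positive.sum()
    pct = np.zeros(n_axes)
    if total > 0:
        for i in range(n_axes):
            pct[i] = 100.0 * eigvals[i] / total if eigvals[i] > _EIG_TOL else 0.0

    return PCoAResult(
        strain_ids=list(d.strain_ids),
        eigenvalues=eigvals,
        coordinates=coords,
        pct_variance=pct,
        negative_eigenvalue_flag=bool((eigvals < -_EIG_TOL).any()),
    )


def variance_captured(r: PCoAResult, k: int) -> float:
    """Percentage of (positive-eigenvalue) variance on the first k axes."""
    if not 0 <= k <= r.n_axes:
        raise ValidationError(f"k must be in [0, {r.n_axes}], got {k}")
    return float(r.pct_variance[:k].sum())
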