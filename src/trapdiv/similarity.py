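"""Pairwise Jaccard similarity among strains and the derived distance matrix.

For two binary band profiles the Jaccard coefficient is ``a / (a + b + c)``
with ``a`` the shared presences and ``b``, ``c`` the presences unique to each
profile; joint absences carry no information about shared ancestry of bands
and are excluded. Downstream clustering and ordination operate on the
complement distance ``d = 1 - s``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from trapdiv.errors import ValidationError
from trapdiv.matrix_io import MarkerMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric strain x strain Jaccard similarities with unit diagonal."""

    strain_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("similarity matrix must be symmetric")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValidationError("similarities must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.strain_ids, columns=self.strain_ids
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="strain")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative strain x strain distances, zero diagonal."""

    strain_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix must be symmetric")
        if (self.values < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.strain_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.strain_ids, columns=self.strain_ids
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="strain")


def jaccard(profile_a, profile_b) -> float:
    """Jaccard similarity of two equal-length binary profiles.

    Both-all-zero profiles have an empty union; the similarity is then
    defined as 0.0 and a warning is logged.
    """
    a = np.asarray(profile_a)
    b = np.asarray(profile_b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError(
            f"profiles must be equal-length 1-D vectors of length >= 1, "
            f"got shapes {a.shape} and {b.shape}"
        )
    for v in (a, b):
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("profiles must be binary (0/1)")
    shared = int(np.sum((a == 1) & (b == 1)))
    union = int(np.sum((a == 1) | (b == 1)))
    if union == 0:
        logger.warning("both profiles are all-zero; Jaccard defined as 0.0")
        return 0.0
    return shared / union


def similarity_matrix(m: MarkerMatrix) -> SimilarityMatrix:
    """All-pairs Jaccard similarity among the strains of a band matrix."""
    x = m.values.astype(np.int64)
    inter = x @ x.T
    counts = x.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    if (np.diag(union) == 0).any():
        logger.warning(
            "matrix contains all-zero strain profiles; their similarities "
            "are defined as 0.0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    # an all-zero strain is identical to nothing, not even itself, but the
    # unit diagonal is part of the similarity-matrix contract
    return SimilarityMatrix(list(m.strain_ids), sim)


def to_distance(s: SimilarityMatrix) -> DistanceMatrix:
    """Complement distance ``d = 1 - s`` with an exact zero diagonal."""
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(s.strain_ids), d)
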