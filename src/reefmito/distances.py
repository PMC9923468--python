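"""Pairwise nucleotide-difference matrices and diversity summaries.

Distances are raw site counts under pairwise deletion: a position contributes
to the distance between two colonies only when both have a called base (A, C,
G or T) there, and the bases differ.  The number of jointly called sites is
tracked alongside so percentage views and identity calls remain meaningful
despite the ~tens of uncalled positions typical of consensus mitogenome
assemblies.  No substitution-model correction is applied; at the divergence
levels involved (<<1%) multiple hits are negligible.

With pairwise deletion the triangle inequality can fail (a site uncalled in
one pair may be called in another); nothing downstream relies on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import InsufficientDataError
from .seqio import Alignment, UNCALLED


@dataclass
class DistanceMatrix:
    """Counts of differing sites (D) and jointly called sites (C)."""

    ids: list[str]
    D: np.ndarray
    C: np.ndarray
    convention: str = "pairwise-deletion site counts"

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.D.shape == (n, n) and self.C.shape == (n, n)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="colony")


def _variable_columns(X: np.ndarray) -> np.ndarray:
    """Boolean mask over columns with >= 2 distinct called bases."""
    distinct = np.zeros(X.shape[1], dtype=np.int8)
    for b in range(4):
        distinct += (X == b).any(axis=0)
    return distinct >= 2


def pairwise_difference_matrix(aln: Alignment) -> DistanceMatrix:
    """Compute D (differing sites) and C (jointly called sites) for all pairs.

    Only columns that are polymorphic among called bases can contribute to D,
    so mismatch counting is restricted to those; C is computed exactly over
    the full alignment via the (sparse) uncalled-position overlap.
    """
    X = aln.encoded()
    n, L = X.shape
    called = X != UNCALLED

    # C_ij = L - u_i - u_j + |uncalled_i ∩ uncalled_j|
    u = (~called).sum(axis=1)
    miss = sp.csr_matrix((~called).astype(np.int64))
    overlap = np.asarray((miss @ miss.T).todense())
    C = L - u[:, None] - u[None, :] + overlap
    np.fill_diagonal(C, L - u)

    var = _variable_columns(X)
    Xv = X[:, var]
    cv = (Xv != UNCALLED).astype(np.float32)
    both = cv @ cv.T
    matches = np.zeros((n, n), dtype=np.float32)
    for b in range(4):
        ind = (Xv == b).astype(np.float32)
        matches += ind @ ind.T
    D = np.rint(both - matches).astype(np.int64)
    np.fill_diagonal(D, 0)
    return DistanceMatrix(list(aln.ids), D, C.astype(np.int64))


def variable_site_count(aln: Alignment) -> int:
    """Number of alignment columns with >= 2 distinct called bases."""
    return int(_variable_columns(aln.encoded()).sum())


def _upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def mean_pairwise_difference(dm: DistanceMatrix) -> float:
    """Arithmetic mean of D over the n(n-1)/2 unordered pairs (in bases)."""
    if dm.n < 2:
        raise InsufficientDataError("mean pairwise difference needs >= 2 sequences")
    return float(_upper(dm.D).mean())


def mean_pairwise_fraction(dm: DistanceMatrix) -> float:
    """Mean pairwise difference as a fraction of the median jointly called sites."""
    if dm.n < 2:
        raise InsufficientDataError("mean pairwise fraction needs >= 2 sequences")
    return float(_upper(dm.D).mean() / np.median(_upper(dm.C)))
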