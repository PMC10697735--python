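"""Phenotype co-occurrence network construction.

Each individual contributes a single-layer graph whose (j, k) edge is 1
when the individual is a case for both phenotypes j and k; summing the
layers over individuals gives the weighted adjacency matrix A, whose
diagonal entry A_jj is the case count of phenotype j.  Individuals with
no case status contribute nothing, so A can be accumulated over the
case-carrying rows only — identical to using the full cohort.

The similarity matrix normalizes co-occurrence by the geometric mean of
the case counts:  W = diag(A)^{-1/2} A diag(A)^{-1/2}, so W_jk in [0, 1]
and W_jj = 1.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["build_adjacency", "similarity", "drop_zero_case_phenotypes"]


def build_adjacency(phenotypes: np.ndarray) -> np.ndarray:
    """Sum per-individual co-case indicator matrices into the K x K adjacency A.

    ``A[j, k]`` counts individuals who are cases for both phenotypes j and
    k; ``A[j, j]`` is the case count of phenotype j.  Only rows with at
    least one case are accumulated (provably the same as using all rows).
    """
    Y = np.asarray(phenotypes)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("phenotype matrix must be n x K with K >= 2")
    if not np.all((Y == 0) | (Y == 1)):
        raise ValueError("phenotype matrix must be binary 0/1")
    active = Y.any(axis=1)
    Yc = Y[active]
    if Yc.shape[0] < (1 << 24):
        # float32 matmul is exact for counts below 2^24 and runs in BLAS
        A = Yc.astype(np.float32).T @ Yc.astype(np.float32)
        return np.rint(A).astype(np.int64)
    return Yc.astype(np.int64).T @ Yc.astype(np.int64)


def drop_zero_case_phenotypes(
    phenotypes: np.ndarray, names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Return (filtered phenotypes, boolean keep-mask), warning on drops.

    Phenotypes with no cases carry no network or association information
    and would make the similarity normalization degenerate.
    """
    Y = np.asarray(phenotypes)
    keep = Y.sum(axis=0) > 0
    if not keep.all():
        dropped = np.flatnonzero(~keep)
        labels = [names[j] for j in dropped] if names is not None else list(dropped)
        warnings.warn(
            f"dropping {len(dropped)} phenotype(s) with zero cases: {labels}",
            stacklevel=2,
        )
    return Y[:, keep], keep


def similarity(adjacency: np.ndarray) -> np.ndarray:
    """Normalize A into W = diag(A)^{-1/2} A diag(A)^{-1/2}.

    Raises if any phenotype has zero cases (zero diagonal), naming the
    offending column.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    diag = np.diag(A)
    if np.any(diag <= 0):
        bad = np.flatnonzero(diag <= 0).tolist()
        raise ValueError(f"phenotype(s) {bad} have zero cases; similarity undefined")
    inv_sqrt = 1.0 / np.sqrt(diag)
    W = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(W, 1.0)
    return W
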