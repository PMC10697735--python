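"""Score tests on merged phenotypes and the omnibus chi-square combination.

For cluster l the association between the merged phenotype Y_l and the
genotype x is measured by the score statistic

    T_l = sqrt(n) * corr(x, Y_l),

which is asymptotically N(0, 1) under the null.  The L statistics are
correlated; their correlation matrix Sigma is estimated by the Pearson
correlation matrix of the merged phenotypes, and the omnibus statistic

    T = (T_1, ..., T_L) Sigma^{-1} (T_1, ..., T_L)^T

is referred to a chi-square distribution with L degrees of freedom.

Covariates (principal components, sex, age, ...) are handled by linear
residualization: both genotype and merged phenotypes are replaced by
their least-squares residuals against the covariates plus intercept
before the score tests, after which the merged phenotypes are continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .community import ClusterAssignment, merge_phenotypes, select_clusters
from .network import build_adjacency, drop_zero_case_phenotypes, similarity

__all__ = [
    "TestResult",
    "residualize",
    "score_test",
    "estimate_sigma",
    "omnibus",
    "mln_o_test",
]

# ridge guard for near-singular merged-phenotype correlation matrices
_SIGMA_COND_MAX = 1e8
_SIGMA_RIDGE = 1e-8


@dataclass(frozen=True)
class TestResult:
    """Omnibus test outcome for one SNP.

    Attributes
    ----------
    statistic : float
        The omnibus quadratic form, >= 0.
    df : int
        Degrees of freedom (number of clusters contributing).
    p_value : float
        Upper-tail chi-square probability.
    cluster_stats : ndarray, shape (L,)
        Per-cluster score statistics T_l.
    sigma : ndarray, shape (L, L)
        Estimated correlation matrix of the score statistics.
    assignment : ClusterAssignment or None
        Phenotype partition used (None when the caller supplied merged data).
    """

    statistic: float
    df: int
    p_value: float
    cluster_stats: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)
    assignment: ClusterAssignment | None = field(default=None, repr=False)


def residualize(target: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Replace each column of ``target`` by its least-squares residual.

    The design is (intercept, covariates); with no covariates the columns
    are simply centered.  Residuals are mean zero and orthogonal to every
    covariate column.
    """
    T = np.asarray(target, dtype=float)
    squeeze = T.ndim == 1
    if squeeze:
        T = T[:, None]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        R = T - T.mean(axis=0)
        return R.ravel() if squeeze else R
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    X = np.column_stack([np.ones(Z.shape[0]), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "covariate design (with intercept) is rank deficient"
        )
    coef, *_ = np.linalg.lstsq(X, T, rcond=None)
    R = T - X @ coef
    return R.ravel() if squeeze else R


def score_test(x: np.ndarray, y: np.ndarray) -> float:
    """sqrt(n) times the Pearson correlation of genotype and merged phenotype.

    Asymptotically standard normal when the genotype has no effect.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("genotype and phenotype must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = xc @ xc
    sy = yc @ yc
    if sx <= 0 or sy <= 0:
        raise ValueError("zero variance in genotype or phenotype")
    return float(np.sqrt(n) * (xc @ yc) / np.sqrt(sx * sy))


def estimate_sigma(merged: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the merged phenotypes (estimates Sigma)."""
    M = np.asarray(merged, dtype=float)
    if M.ndim != 2:
        raise ValueError("merged phenotype matrix must be 2-dimensional")
    if M.shape[1] == 1:
        if M[:, 0].std() == 0:
            raise ValueError("merged phenotype has zero variance")
        return np.ones((1, 1))
    sd = M.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"merged phenotype(s) {bad} have zero variance")
    sigma = np.corrcoef(M, rowvar=False)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _guarded_inverse(sigma: np.ndarray) -> np.ndarray:
    """Invert Sigma, adding a tiny ridge when it is numerically singular."""
    if np.linalg.cond(sigma) > _SIGMA_COND_MAX:
        warnings.warn(
            "near-singular merged-phenotype correlation matrix; "
            f"adding ridge {_SIGMA_RIDGE:g} to the diagonal",
            stacklevel=3,
        )
        sigma = sigma + _SIGMA_RIDGE * np.eye(sigma.shape[0])
    return np.linalg.inv(sigma)


def omnibus(
    cluster_stats: np.ndarray,
    sigma: np.ndarray,
    assignment: ClusterAssignment | None = None,
) -> TestResult:
    """Combine per-cluster score statistics into the chi-square omnibus test.

    statistic = T Sigma^{-1} T^T, referred to chi-square with L degrees
    of freedom.
    """
    T = np.atleast_1d(np.asarray(cluster_stats, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    L = T.shape[0]
    if sigma.shape != (L, L):
        raise ValueError(f"sigma must be {L} x {L}, got {sigma.shape}")
    stat = float(T @ _guarded_inverse(sigma) @ T)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=L))
    return TestResult(
        statistic=stat,
        df=L,
        p_value=p,
        cluster_stats=T,
        sigma=sigma,
        assignment=assignment,
    )


def mln_o_test(
    genotype: np.ndarray,
    phenotypes: np.ndarray,
    covariates: np.ndarray | None = None,
    assignment: ClusterAssignment | None = None,
    include_self_loops: bool = False,
) -> TestResult:
    """Full pipeline: network -> clustering -> merging -> score tests -> omnibus.

    Parameters
    ----------
    genotype : ndarray, shape (n,)
        Minor-allele counts 0/1/2 (or residualized dosages).
    phenotypes : ndarray, shape (n, K)
        Binary case indicators; zero-case columns are dropped with a warning.
    covariates : ndarray, shape (n, p), optional
        If given, genotype and merged phenotypes are residualized on
        (intercept, covariates) before testing.
    assignment : ClusterAssignment, optional
        Reuse a precomputed phenotype partition (e.g. across SNPs of a
        scan); by default the partition is derived from ``phenotypes``.
    include_self_loops : bool
        Forwarded to :func:`~mlno.community.select_clusters`.
    """
    x = np.asarray(genotype, dtype=float)
    Y = np.asarray(phenotypes)
    if Y.ndim != 2 or Y.shape[0] != x.shape[0]:
        raise ValueError("phenotype matrix must be n x K matching the genotype")
    Y, _ = drop_zero_case_phenotypes(Y)
    if assignment is None:
        W = similarity(build_adjacency(Y))
        assignment = select_clusters(W, include_self_loops=include_self_loops)
    merged = merge_phenotypes(Y, assignment).astype(float)
    if covariates is not None:
        x = residualize(x, covariates)
        merged = residualize(merged, covariates)
    # drop clusters whose merged phenotype is constant (degenerate subset)
    sd = merged.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = np.flatnonzero(~keep).tolist()
        warnings.warn(
            f"dropping {len(dropped)} constant merged phenotype(s) {dropped}; "
            "degrees of freedom reduced",
            stacklevel=2,
        )
        merged = merged[:, keep]
        if merged.shape[1] == 0:
            raise ValueError("all merged phenotypes are constant; test undefined")
    T = np.array([score_test(x, merged[:, l]) for l in range(merged.shape[1])])
    sigma = estimate_sigma(merged)
    return omnibus(T, sigma, assignment=assignment)
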