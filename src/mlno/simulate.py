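"""Synthetic genotype/phenotype generation for unbalanced multi-phenotype studies.

Genotypes are minor-allele counts drawn under Hardy-Weinberg equilibrium.
Quantitative liabilities follow a block factor model

    y = lambda * x + c * gamma f + sqrt(1 - c^2) * eps,

where ``f`` is an R-vector of factors with exchangeable covariance
``(1 - rho) I + rho J`` and ``eps`` is iid standard normal.  With effect
size beta = 0 this induces a within-factor phenotype correlation of c^2
and a between-factor correlation of rho * c^2.  Binary case status is
assigned by a liability threshold: per phenotype, the top round(n*r)
liabilities become cases, so every column has exactly that many cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FactorModelSpec",
    "simulate_genotypes",
    "build_effect_spec",
    "simulate_quantitative",
    "dichotomize",
]


@dataclass(frozen=True)
class FactorModelSpec:
    """Effect vector and factor-loading structure for one simulation model.

    Attributes
    ----------
    K : int
        Number of phenotypes.
    R : int
        Number of latent factors; ``K`` must be divisible by ``R``.
    lam : ndarray, shape (K,)
        Genotype effect on each liability (the vector lambda).
    gamma : ndarray, shape (K, R)
        0/1 block-diagonal loading matrix; each row has exactly one 1.
    c : float
        Within-factor loading constant, 0 <= c <= 1.
    rho : float
        Correlation between factors, -1/(R-1) < rho <= 1.
    beta : float
        Scalar effect size the model was built from (0 under the null).
    """

    K: int
    R: int
    lam: np.ndarray = field(repr=False)
    gamma: np.ndarray = field(repr=False)
    c: float
    rho: float
    beta: float

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        gamma = np.asarray(self.gamma)
        if lam.shape != (self.K,):
            raise ValueError(f"lambda must have shape ({self.K},), got {lam.shape}")
        if gamma.shape != (self.K, self.R):
            raise ValueError(
                f"gamma must have shape ({self.K}, {self.R}), got {gamma.shape}"
            )
        if not np.all((gamma == 0) | (gamma == 1)) or not np.all(gamma.sum(axis=1) == 1):
            raise ValueError("gamma rows must be 0/1 with exactly one 1 per row")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must lie in [0, 1], got {self.c}")
        if not (-1.0 / (self.R - 1) if self.R > 1 else -np.inf) < self.rho <= 1.0:
            raise ValueError(
                f"rho={self.rho} gives a non-positive-definite factor covariance"
            )
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "gamma", gamma.astype(np.int8))

    @property
    def factor_index(self) -> np.ndarray:
        """Length-K index of the factor each phenotype loads on."""
        return np.argmax(self.gamma, axis=1)


def simulate_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """Draw ``n`` minor-allele counts (0/1/2) under Hardy-Weinberg equilibrium.

    P(2) = maf^2, P(1) = 2 maf (1-maf), P(0) = (1-maf)^2.

    Parameters
    ----------
    n : int
        Sample size.
    maf : float
        Minor-allele frequency, in (0, 0.5].
    seed : int, SeedSequence, Generator, optional
        Randomness source; anything :func:`numpy.random.default_rng` accepts.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must lie in (0, 0.5], got {maf}")
    rng = np.random.default_rng(seed)
    # sum of two independent allele draws == binomial(2, maf) per individual
    return rng.binomial(2, maf, size=n).astype(np.int8)


def _block_effects(model_id: int, K: int, beta: float) -> tuple[int, np.ndarray]:
    """Return (R, lambda) for the five standard effect configurations."""
    if model_id in (1, 2, 3):
        R = 5
    elif model_id == 4:
        R = 10
    elif model_id == 5:
        R = 50
    else:
        raise ValueError(f"model_id must be 1..5, got {model_id}")
    if K % R != 0:
        raise ValueError(f"K={K} is not divisible by R={R} for model {model_id}")
    k = K // R
    lam = np.zeros(K)
    if model_id == 1:
        # two trailing factors share the same positive effect
        lam[3 * k :] = beta
    elif model_id == 2:
        lam[3 * k : 4 * k] = -beta
        lam[4 * k :] = beta
    elif model_id == 3:
        lam[3 * k : 4 * k] = -beta
        lam[4 * k :] = (2.0 * beta / (k + 1)) * np.arange(1, k + 1)
    elif model_id == 4:
        if k % 2 != 0:
            raise ValueError(f"model 4 needs an even block size, got k={k}")
        tri = np.concatenate([np.arange(1, k // 2 + 1), np.arange(k // 2, 0, -1)])
        ramp = tri / (k / 2 + 1)
        lam[6 * k : 7 * k] = -beta * ramp
        lam[7 * k : 8 * k] = beta * ramp
        lam[8 * k : 9 * k] = -beta
        lam[9 * k :] = beta
    else:  # model 5: 50 factors of size K/50; last ten factors split +/-beta
        lam[40 * k : 45 * k] = beta
        lam[45 * k :] = -beta
    return R, lam


def build_effect_spec(
    model_id: int,
    K: int = 100,
    beta: float = 0.0,
    *,
    c2: float = 0.4,
    rho_c2: float = 0.24,
) -> FactorModelSpec:
    """Build the :class:`FactorModelSpec` for one of the five standard models.

    Models 1-3 use R=5 factors, model 4 uses R=10, model 5 uses R=50; the
    genotype effect is confined to the trailing factors with signs and
    tapers specific to each model.  ``c2`` is the within-factor phenotype
    correlation (c^2) and ``rho_c2`` the between-factor correlation
    (rho * c^2); the defaults are the standard study conditions.
    """
    if not 0.0 < c2 <= 1.0:
        raise ValueError(f"within-factor correlation c2 must be in (0, 1], got {c2}")
    R, lam = _block_effects(model_id, K, beta)
    k = K // R
    gamma = np.kron(np.eye(R, dtype=np.int8), np.ones((k, 1), dtype=np.int8))
    c = float(np.sqrt(c2))
    rho = rho_c2 / c2
    return FactorModelSpec(K=K, R=R, lam=lam, gamma=gamma, c=c, rho=rho, beta=beta)


def simulate_quantitative(
    spec: FactorModelSpec, genotypes: np.ndarray, seed=None, dtype=np.float64
) -> np.ndarray:
    """Draw the n x K liability matrix y = lambda x + c gamma f + sqrt(1-c^2) eps.

    The factor vector f has the exchangeable covariance (1-rho) I + rho J,
    realised as ``sqrt(1-rho) z + sqrt(rho) z0`` with ``z0`` shared across
    the R factors of an individual (valid for rho >= 0; a dense Cholesky
    is used for rho < 0).  ``dtype`` may be ``numpy.float32`` for large
    Monte-Carlo runs; ranks, not magnitudes, feed the dichotomization.
    """
    x = np.asarray(genotypes, dtype=dtype)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    R, K = spec.R, spec.K
    if spec.rho >= 0.0:
        f = rng.standard_normal((n, R), dtype=dtype)
        f *= np.sqrt(1.0 - spec.rho)
        if spec.rho > 0.0:
            f += np.sqrt(spec.rho, dtype=dtype) * rng.standard_normal((n, 1), dtype=dtype)
    else:
        cov = (1.0 - spec.rho) * np.eye(R) + spec.rho
        chol = np.linalg.cholesky(cov)
        f = (rng.standard_normal((n, R)) @ chol.T).astype(dtype)
    y = rng.standard_normal((n, K), dtype=dtype)
    y *= np.sqrt(1.0 - spec.c**2)
    y += dtype(spec.c) * f[:, spec.factor_index]
    if np.any(spec.lam):
        y += x[:, None] * spec.lam[None, :].astype(dtype)
    return y


def _case_count(n: int, r: float) -> int:
    """round-half-to-even case count; n*r is integral in all standard settings."""
    if not 0.0 < r < 1.0:
        raise ValueError(f"case-control ratio must lie in (0, 1), got {r}")
    m = int(round(n * r))
    if m < 1:
        raise ValueError(f"n*r = {n * r:g} rounds to zero cases; increase n or r")
    return m


def dichotomize(liabilities: np.ndarray, r: float) -> np.ndarray:
    """Threshold liabilities so each column has exactly round(n*r) cases.

    Per phenotype, the individuals with the largest liabilities are cases.
    Ties at the threshold (probability zero under the continuous model)
    are broken by smallest row index so the output is deterministic.
    """
    y = np.asarray(liabilities, dtype=float)
    if y.ndim != 2:
        raise ValueError("liability matrix must be 2-dimensional")
    n, K = y.shape
    m = _case_count(n, r)
    # the m-th largest value per column via a partial sort, O(nK)
    part = np.partition(y, n - m, axis=0)
    thresh = part[n - m, :]
    ge = y >= thresh[None, :]
    counts = ge.sum(axis=0)
    out = ge.astype(np.int8)
    # boundary ties (several entries equal to the threshold) have
    # probability zero under the continuous model; resolve them by
    # keeping the smallest row indices so the output is deterministic
    for j in np.flatnonzero(counts != m):
        col = y[:, j]
        strict = np.flatnonzero(col > thresh[j])
        tied = np.flatnonzero(col == thresh[j])
        out[:, j] = 0
        out[np.concatenate([strict, tied[: m - strict.size]]), j] = 1
    return out
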