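"""Reference multi-phenotype association tests used for comparison.

Four standard joint tests of K phenotypes against a single SNP:

* MANOVA — Wilks' Lambda from the one-predictor multivariate regression,
  referred to chi-square with K df via the Bartlett transform.
* USAT — minimum-p combination of MANOVA with the sum-of-squared-scores
  (SSU) statistic over a grid of mixing weights.
* TATES — extended Simes combination of per-phenotype p-values using
  effective numbers of tests from the p-value correlation matrix.
* MultiPhen — proportional-odds regression of the genotype categories on
  all phenotypes, likelihood-ratio chi-square with K df.

These are implementations from the published descriptions, intended for
simulation comparison, not ports of the original authors' code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

__all__ = [
    "ComparatorResult",
    "manova_test",
    "usat_test",
    "tates_test",
    "multiphen_test",
]


@dataclass(frozen=True)
class ComparatorResult:
    """Outcome of one comparator test for one SNP."""

    method: str
    statistic: float
    df: float
    p_value: float
    converged: bool = True
    details: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# shared cross-products, exploiting sparsity of extremely unbalanced 0/1 data


def _centered_crossproducts(x, Y):
    """Return (S_yy, s_xy, s_xx, n) for centered Y (n x K) and x (n,).

    When Y is binary with rare cases, Y'Y and Y'x are accumulated over
    case-carrying rows only, which keeps genome-scale use cheap.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y)
    n, K = Y.shape
    ybar = Y.mean(axis=0, dtype=float)
    xbar = x.mean()
    if Y.dtype.kind in "iub" and ybar.mean() < 0.2:
        active = Y.any(axis=1)
        Ya = Y[active].astype(float)
        G = Ya.T @ Ya
        xy = Ya.T @ x[active]
    else:
        Yf = Y.astype(float)
        G = Yf.T @ Yf
        xy = Yf.T @ x
    S_yy = G - n * np.outer(ybar, ybar)
    s_xy = xy - n * ybar * xbar
    s_xx = float(x @ x - n * xbar**2)
    return S_yy, s_xy, s_xx, n


def _wilks_lambda(x, Y):
    S_yy, s_xy, s_xx, n = _centered_crossproducts(x, Y)
    if s_xx <= 0:
        raise ValueError("genotype has zero variance")
    try:
        quad = float(s_xy @ np.linalg.solve(S_yy, s_xy))
    except np.linalg.LinAlgError:
        # collinear phenotype columns: ridge-guard the within covariance
        ridge = 1e-8 * np.trace(S_yy) / S_yy.shape[0]
        quad = float(s_xy @ np.linalg.solve(S_yy + ridge * np.eye(S_yy.shape[0]), s_xy))
    lam = 1.0 - quad / s_xx
    return float(np.clip(lam, np.finfo(float).tiny, 1.0)), n


def manova_test(genotype, phenotypes) -> ComparatorResult:
    """Wilks' Lambda MANOVA of all phenotypes on the genotype.

    With a single predictor Lambda = 1 - R^2 of the genotype on the
    phenotype span; Bartlett's -(n - 1 - (K+2)/2) log Lambda is referred
    to chi-square with K degrees of freedom.
    """
    Y = np.asarray(phenotypes)
    K = Y.shape[1]
    lam, n = _wilks_lambda(genotype, Y)
    stat = -(n - 1 - (K + 2) / 2.0) * np.log(lam)
    p = float(stats.chi2.sf(stat, df=K))
    return ComparatorResult("MANOVA", float(stat), K, p, details={"wilks_lambda": lam})


# ---------------------------------------------------------------------------
# USAT


def _per_phenotype_scores(x, Y):
    """Standardized per-phenotype score statistics U_k = sqrt(n) corr(x, y_k)."""
    S_yy, s_xy, s_xx, n = _centered_crossproducts(x, Y)
    sd = np.sqrt(np.diag(S_yy))
    if s_xx <= 0 or np.any(sd <= 0):
        raise ValueError("zero variance in genotype or a phenotype")
    U = np.sqrt(n) * s_xy / (np.sqrt(s_xx) * sd)
    V = S_yy / np.outer(sd, sd)
    np.fill_diagonal(V, 1.0)
    return U, V, n


def _wquad_pvalue(q, weights):
    """Three-moment (shifted scaled chi-square) tail for sum_i w_i chi2_1."""
    c1 = weights.sum()
    c2 = (weights**2).sum()
    c3 = (weights**3).sum()
    if c3 <= 0:
        return float(stats.chi2.sf(q * len(weights) / c1, df=len(weights)))
    a = c3 / c2
    b = c1 - c2**2 / c3
    d = c2**3 / c3**2
    return float(stats.chi2.sf((q - b) / a, df=d))


def _wquad_quantile(p, weights):
    c1 = weights.sum()
    c2 = (weights**2).sum()
    c3 = (weights**3).sum()
    a = c3 / c2
    b = c1 - c2**2 / c3
    d = c2**3 / c3**2
    return a * stats.chi2.isf(p, df=d) + b


_USAT_GRID = np.round(np.arange(0.0, 1.01, 0.1), 1)


def usat_test(genotype, phenotypes, weights_grid=None) -> ComparatorResult:
    """Unified score-based test: min-p combination of MANOVA and SSU.

    T_w = w T_MANOVA + (1-w) T_SSU over w in {0, 0.1, ..., 1}; under the
    null each T_w is a weighted chi-square quadratic form whose p-value
    is obtained by a three-moment match, and the minimum-p statistic is
    calibrated by one-dimensional integration over the MANOVA component
    (treated as independent of SSU — an approximation that errs
    conservative under positive dependence).
    """
    grid = _USAT_GRID if weights_grid is None else np.asarray(weights_grid, float)
    U, V, n = _per_phenotype_scores(genotype, phenotypes)
    K = U.shape[0]
    evals = np.clip(np.linalg.eigvalsh(V), 0.0, None)
    t_ssu = float(U @ U)
    try:
        t_man = float(U @ np.linalg.solve(V, U))
    except np.linalg.LinAlgError:
        t_man = float(U @ np.linalg.lstsq(V, U, rcond=None)[0])
    p_w = np.empty(grid.shape[0])
    for i, w in enumerate(grid):
        t_obs = w * t_man + (1.0 - w) * t_ssu
        wts = w + (1.0 - w) * evals
        p_w[i] = _wquad_pvalue(t_obs, wts)
    p_min = float(p_w.min())
    p_final = _usat_minp_calibration(p_min, grid, evals, K)
    return ComparatorResult(
        "USAT",
        statistic=p_min,
        df=float(K),
        p_value=p_final,
        details={"p_w": p_w, "t_manova": t_man, "t_ssu": t_ssu},
    )


def _usat_minp_calibration(p_min, grid, evals, K):
    """P(min_w p_w <= p_min) by integrating over the chi-square(K) component."""
    if p_min >= 1.0:
        return 1.0
    # per-w quantiles of T_w at level p_min
    q_w = np.array(
        [_wquad_quantile(p_min, w + (1.0 - w) * evals) for w in grid]
    )
    interior = grid < 1.0
    has_manova_end = bool(np.any(grid == 1.0))
    q1 = q_w[grid == 1.0][0] if has_manova_end else np.inf
    w_in = grid[interior]
    q_in = q_w[interior]
    if w_in.size == 0:
        return p_min  # grid is only w=1: pure MANOVA
    ssu_weights = evals

    def joint_survival(t):
        # given T_MANOVA = t, all interior constraints bound T_SSU
        bound = np.min((q_in - w_in * t) / (1.0 - w_in))
        if bound <= 0:
            return 0.0
        return 1.0 - _wquad_pvalue(bound, ssu_weights)

    upper = q1 if np.isfinite(q1) else stats.chi2.isf(1e-14, df=K)
    val, _ = integrate.quad(
        lambda t: joint_survival(t) * stats.chi2.pdf(t, df=K),
        0.0,
        upper,
        limit=100,
    )
    return float(np.clip(1.0 - val, p_min, min(1.0, p_min * grid.size)))


# ---------------------------------------------------------------------------
# TATES

# polynomial mapping phenotype correlation -> p-value correlation (from the
# original extended-Simes construction), powers 1..6
_TATES_POLY = np.array([-0.0009, 0.6281, 0.0099, 0.0588, -0.0127, 0.2982])


def _effective_number(corr):
    """K minus the excess over 1 of the large eigenvalues of ``corr``."""
    evals = np.linalg.eigvalsh(corr)
    excess = evals[evals > 1.0] - 1.0
    return corr.shape[0] - excess.sum()


def tates_test(genotype, phenotypes) -> ComparatorResult:
    """Extended Simes combination of per-phenotype score-test p-values.

    Per-phenotype two-sided normal p-values are ordered; the p-value
    correlation matrix is approximated from the phenotype correlation
    matrix by a sixth-order polynomial, and effective numbers of tests
    K_e (all phenotypes) and K_e_i (top-i) rescale the Simes bound:
    p = min_i K_e p_(i) / K_e_i.
    """
    U, V, n = _per_phenotype_scores(genotype, phenotypes)
    K = U.shape[0]
    p_uni = 2.0 * stats.norm.sf(np.abs(U))
    if K == 1:
        return ComparatorResult("TATES", float(p_uni[0]), 1.0, float(p_uni[0]))
    r_p = np.zeros_like(V)
    for power, coef in enumerate(_TATES_POLY, start=1):
        r_p += coef * V**power
    # the fitted polynomial maps |r|=1 to ~0.98; identical tests have
    # perfectly correlated p-values, so pin the endpoints
    r_p[np.abs(V) >= 1.0 - 1e-12] = 1.0
    np.fill_diagonal(r_p, 1.0)
    order = np.argsort(p_uni, kind="stable")
    p_sorted = p_uni[order]
    r_sorted = r_p[np.ix_(order, order)]
    ke = _effective_number(r_sorted)
    ratios = np.empty(K)
    for i in range(1, K + 1):
        ke_i = _effective_number(r_sorted[:i, :i])
        ratios[i - 1] = ke * p_sorted[i - 1] / ke_i
    p = float(min(1.0, ratios.min()))
    return ComparatorResult(
        "TATES", statistic=p, df=float(ke), p_value=p, details={"k_effective": ke}
    )


# ---------------------------------------------------------------------------
# MultiPhen: proportional-odds regression of genotype on phenotypes


def _aggregate_rows(x, Y):
    """Collapse identical phenotype rows into weighted pseudo-observations.

    With extremely unbalanced phenotypes almost every row is all-zero, so
    the ordinal fit reduces to a few thousand distinct rows regardless of
    the cohort size.  Returns (patterns m x K, counts m x J, categories).
    """
    x = np.asarray(x)
    Y = np.asarray(Y)
    cats, x_idx = np.unique(x, return_inverse=True)
    J = cats.shape[0]
    active = Y.any(axis=1)
    counts0 = np.bincount(x_idx[~active], minlength=J).astype(float)
    X = np.zeros((1, Y.shape[1]))
    N = counts0[None, :]
    if active.any():
        uniq, inv = np.unique(Y[active], axis=0, return_inverse=True)
        cnt = np.zeros((uniq.shape[0], J))
        np.add.at(cnt, (inv, x_idx[active]), 1.0)
        X = np.vstack([X, uniq.astype(float)])
        N = np.vstack([N, cnt])
    keep = N.sum(axis=1) > 0
    return X[keep], N[keep], cats


def _polr_loglik_parts(theta, eta, N):
    """Log-likelihood, score and expected information of the cumulative model.

    theta: J-1 increasing cutpoints; eta: m linear predictors; N: m x J
    category counts.  Returns (loglik, score over (theta, eta-weights),
    information blocks) in the (theta, eta) parametrization.
    """
    m, J = N.shape
    G = 1.0 / (1.0 + np.exp(-(theta[None, :] - eta[:, None])))  # m x (J-1)
    Gfull = np.concatenate([np.zeros((m, 1)), G, np.ones((m, 1))], axis=1)
    pi = np.clip(np.diff(Gfull, axis=1), 1e-300, None)  # m x J
    ll = float((N * np.log(pi)).sum())
    u = G * (1.0 - G)  # logistic densities at cutpoints, m x (J-1)
    # category score vectors wrt (theta_0..theta_{J-2}, eta)
    # d log pi_j / d theta_t = (delta_{t,j} u_t - delta_{t,j-1} u_t) / pi_j
    # d log pi_j / d eta    = (u_{j-1} - u_j) / pi_j   (u_{-1}=u_{J-1}=0)
    upad = np.concatenate([np.zeros((m, 1)), u, np.zeros((m, 1))], axis=1)  # m x (J+1)
    d_eta = (upad[:, :-1] - upad[:, 1:]) / pi  # m x J
    n_r = N.sum(axis=1)
    score_theta = np.zeros(J - 1)
    info_tt = np.zeros((J - 1, J - 1))
    info_te_rows = np.zeros((m, J - 1))
    for t in range(J - 1):
        d_t = np.zeros((m, J))
        d_t[:, t] += u[:, t] / pi[:, t]
        d_t[:, t + 1] -= u[:, t] / pi[:, t + 1]
        score_theta[t] = (N * d_t).sum()
        info_te_rows[:, t] = (pi * d_t * d_eta).sum(axis=1)
        for s in range(t, J - 1):
            d_s = np.zeros((m, J))
            d_s[:, s] += u[:, s] / pi[:, s]
            d_s[:, s + 1] -= u[:, s] / pi[:, s + 1]
            val = (n_r * (pi * d_t * d_s).sum(axis=1)).sum()
            info_tt[t, s] = info_tt[s, t] = val
    score_eta = (N * d_eta).sum(axis=1)  # per-row score wrt eta
    info_ee = n_r * (pi * d_eta**2).sum(axis=1)  # per-row info wrt eta
    info_te_rows *= n_r[:, None]
    return ll, score_theta, score_eta, info_tt, info_te_rows, info_ee


def _fit_polr(X, N, max_iter=100, tol=1e-8):
    """Fisher-scoring fit of the proportional-odds model eta = X b."""
    m, K = X.shape
    J = N.shape[1]
    tot = N.sum(axis=0)
    cum = np.cumsum(tot)[:-1] / tot.sum()
    theta = np.log(cum / (1.0 - cum))
    b = np.zeros(K)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ b
        ll, s_th, s_eta_rows, i_tt, i_te_rows, i_ee_rows = _polr_loglik_parts(
            theta, eta, N
        )
        grad = np.concatenate([s_th, X.T @ s_eta_rows])
        i_tb = i_te_rows.T @ X
        i_bb = (X * i_ee_rows[:, None]).T @ X
        info = np.block([[i_tt, i_tb], [i_tb.T, i_bb]])
        if np.linalg.norm(grad) < tol and ll >= ll_old - 1e-12:
            converged = True
            break
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(info.shape[0]), grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps cutpoints ordered and the likelihood ascending
        scale = 1.0
        for _half in range(30):
            th_new = theta + scale * step[: J - 1]
            b_new = b + scale * step[J - 1 :]
            if np.all(np.diff(th_new) > 0):
                ll_new = _polr_loglik_only(th_new, X @ b_new, N)
                if ll_new >= ll - 1e-10:
                    break
            scale *= 0.5
        theta = theta + scale * step[: J - 1]
        b = b + scale * step[J - 1 :]
        ll_old = ll
    eta = X @ b
    ll = _polr_loglik_only(theta, eta, N)
    return theta, b, ll, converged


def _polr_loglik_only(theta, eta, N):
    m = eta.shape[0]
    G = 1.0 / (1.0 + np.exp(-(theta[None, :] - eta[:, None])))
    Gfull = np.concatenate([np.zeros((m, 1)), G, np.ones((m, 1))], axis=1)
    pi = np.clip(np.diff(Gfull, axis=1), 1e-300, None)
    return float((N * np.log(pi)).sum())


def multiphen_test(genotype, phenotypes, max_iter=100, tol=1e-8) -> ComparatorResult:
    """Proportional-odds regression of genotype categories on all phenotypes.

    Likelihood-ratio test of the K phenotype coefficients against the
    intercepts-only model, referred to chi-square with K df.  Genotypes
    with only two observed categories degrade gracefully to binary
    logistic regression.  Non-convergence is flagged, not raised.
    """
    X, N, cats = _aggregate_rows(genotype, phenotypes)
    K = X.shape[1]
    if cats.shape[0] < 2:
        raise ValueError("genotype must have at least two observed categories")
    # intercept-only MLE reproduces the empirical category proportions
    tot = N.sum(axis=0)
    p0 = tot / tot.sum()
    ll0 = float((tot * np.log(p0)).sum())
    theta, b, ll1, converged = _fit_polr(X, N, max_iter=max_iter, tol=tol)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lrt, df=K))
    return ComparatorResult(
        "MultiPhen",
        statistic=lrt,
        df=float(K),
        p_value=p,
        converged=converged,
        details={"coefficients": b, "cutpoints": theta},
    )
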