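"""Monte-Carlo type-I-error and power studies for the joint-association tests.

Each replicate draws a fresh genotype under HWE and a fresh phenotype
matrix from the block factor model, runs the configured tests, and
records their p-values.  Randomness is keyed per replicate index from
the master seed (``SeedSequence([seed, replicate])``), so results are
identical regardless of execution order or chunking.

Study conditions default to the standard simulation design: K = 100
phenotypes, MAF = 0.3, within-factor correlation c^2 = 0.4,
between-factor correlation rho c^2 = 0.24, case-control ratio r in
{0.001, 0.002}, sample size n in {20000, 30000}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import comparators
from .assoc import mln_o_test
from .simulate import build_effect_spec, dichotomize, simulate_genotypes, simulate_quantitative

__all__ = [
    "ExperimentConfig",
    "METHODS",
    "run_replicate",
    "run_type1",
    "run_power",
    "confidence_band",
]


METHODS = ("MLN-O", "MANOVA", "USAT", "TATES", "MultiPhen")


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for one simulation study.

    ``beta`` may be a scalar (type-I error when 0) or a grid (power
    curve).  ``alpha_levels`` are the nominal significance levels at
    which rejection fractions are tabulated.
    """

    model_id: int = 1
    n: int = 20000
    K: int = 100
    r: float = 0.001
    maf: float = 0.3
    c2: float = 0.4
    rho_c2: float = 0.24
    beta: float | tuple = 0.0
    replicates: int = 2000
    alpha_levels: tuple = (0.05, 0.01)
    methods: tuple = ("MLN-O",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for a in self.alpha_levels:
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha level {a} outside (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


_METHOD_FUNCS = {
    "MANOVA": comparators.manova_test,
    "USAT": comparators.usat_test,
    "TATES": comparators.tates_test,
    "MultiPhen": comparators.multiphen_test,
}


def run_replicate(config: ExperimentConfig, replicate: int, beta: float) -> dict:
    """Simulate one dataset and return {method: p-value} (NaN on failure)."""
    seed = np.random.SeedSequence([config.seed, replicate])
    rng = np.random.default_rng(seed)
    spec = build_effect_spec(
        config.model_id, config.K, beta, c2=config.c2, rho_c2=config.rho_c2
    )
    x = simulate_genotypes(config.n, config.maf, rng)
    # float32 liabilities: dichotomization only uses ranks, and single
    # precision halves the cost of the dominant random draws
    liab = simulate_quantitative(spec, x, rng, dtype=np.float32)
    Y = dichotomize(liab, config.r)
    out = {}
    for method in config.methods:
        try:
            if method == "MLN-O":
                out[method] = mln_o_test(x, Y).p_value
            else:
                res = _METHOD_FUNCS[method](x, Y)
                out[method] = res.p_value if res.converged else np.nan
        except (ValueError, np.linalg.LinAlgError):
            out[method] = np.nan
    return out


def _tabulate(pvals: pd.DataFrame, config: ExperimentConfig, by: str, key) -> pd.DataFrame:
    rows = []
    reps = len(pvals)
    for method in config.methods:
        p = pvals[method]
        failed = int(p.isna().sum())
        for alpha in config.alpha_levels:
            # failures count as non-rejections; denominator is all replicates
            rate = float((p < alpha).sum()) / reps
            rows.append(
                {
                    "method": method,
                    "model": config.model_id,
                    "n": config.n,
                    "r": config.r,
                    by: key,
                    "alpha": alpha,
                    "rejection_rate": rate,
                    "mc_se": float(np.sqrt(rate * (1.0 - rate) / reps)),
                    "replicates": reps,
                    "failures": failed,
                }
            )
    return pd.DataFrame(rows)


def run_type1(config: ExperimentConfig, progress=None) -> pd.DataFrame:
    """Null study: rejection fractions at each alpha level with beta = 0."""
    records = []
    for rep in range(config.replicates):
        records.append(run_replicate(config, rep, beta=0.0))
        if progress is not None:
            progress(rep)
    pvals = pd.DataFrame.from_records(records)
    table = _tabulate(pvals, config, by="beta", key=0.0)
    return table.drop(columns="beta")


def run_power(config: ExperimentConfig, progress=None) -> pd.DataFrame:
    """Power study over a beta grid at the configured alpha levels."""
    betas = np.atleast_1d(np.asarray(config.beta, dtype=float))
    if betas.size == 0:
        raise ValueError("beta grid must be nonempty for a power study")
    tables = []
    for b in betas:
        records = [
            run_replicate(config, rep, beta=float(b))
            for rep in range(config.replicates)
        ]
        if progress is not None:
            progress(b)
        tables.append(_tabulate(pd.DataFrame.from_records(records), config, "beta", float(b)))
    return pd.concat(tables, ignore_index=True)


def confidence_band(alpha: float, reps: int, digits: int | None = 5):
    """Normal-approximation 95% band for a Monte-Carlo rejection estimate.

    alpha +/- 1.96 sqrt(alpha (1 - alpha) / reps), rounded for display.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    half = 1.96 * np.sqrt(alpha * (1.0 - alpha) / reps)
    lo, hi = alpha - half, alpha + half
    if digits is not None:
        lo, hi = round(lo, digits), round(hi, digits)
    return lo, hi
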