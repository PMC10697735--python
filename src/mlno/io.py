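"""Tab-delimited input/output for phenotype, genotype and covariate tables.

All tables are plain text with a header row and a leading individual-ID
column.  Genotypes are additionally accepted in the PLINK additive
text-export dialect (header ``FID IID PAT MAT SEX PHENOTYPE <SNP>_A ...``,
whitespace-delimited, missing calls coded NA); rows with missing
genotypes are dropped with a logged count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix",
    "write_assignment",
    "read_phenotypes",
    "read_genotypes",
    "read_covariates",
    "align_ids",
]

log = logging.getLogger(__name__)

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_matrix(path, values, columns, ids=None, id_name="IID") -> None:
    """Write an n x m matrix as tab-delimited text with an ID column."""
    values = np.asarray(values)
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, columns=list(columns))
    df.insert(0, id_name, list(ids))
    df.to_csv(path, sep="\t", index=False)


def write_assignment(path, assignment, names=None, curve_path=None) -> None:
    """Write a phenotype->cluster table; optionally the (k0, Q) curve too."""
    labels = assignment.labels
    if names is None:
        names = [f"pheno{j + 1}" for j in range(labels.shape[0])]
    pd.DataFrame({"phenotype": list(names), "cluster": labels}).to_csv(
        path, sep="\t", index=False
    )
    if curve_path is not None and assignment.modularity_curve is not None:
        curve = assignment.modularity_curve
        pd.DataFrame(
            {"n_clusters": np.arange(1, curve.shape[0] + 1), "modularity": curve}
        ).to_csv(curve_path, sep="\t", index=False)


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an ID column plus data columns")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Read a binary phenotype table (ID column then 0/1 phenotype columns)."""
    df = _read_table(path)
    idc = df.columns[0]
    data = df.set_index(idc)
    try:
        arr = data.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric phenotype entry ({exc})") from None
    bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-binary phenotype value {arr[i, j]!r} at row "
            f"{data.index[i]!r}, column {data.columns[j]!r}"
        )
    return pd.DataFrame(arr.astype(np.int8), index=data.index, columns=data.columns)


def read_genotypes(path) -> pd.DataFrame:
    """Read genotype dosages; plain ID+SNP tables or the PLINK .raw dialect.

    Values must be 0/1/2 or missing (NA); rows with any missing genotype
    are dropped with a logged count.
    """
    df = _read_table(path)
    if list(df.columns[:2]) == ["FID", "IID"]:
        meta = [c for c in _PLINK_META if c in df.columns]
        ids = df["IID"]
        snps = df.drop(columns=meta)
    else:
        ids = df.iloc[:, 0]
        snps = df.iloc[:, 1:]
    arr = snps.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    missing = np.isnan(arr).any(axis=1)
    if missing.any():
        log.warning("%s: dropped %d row(s) with missing genotypes", path, missing.sum())
        arr = arr[~missing]
        ids = ids[~missing]
    bad = ~np.isin(arr, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: genotype value {arr[i, j]!r} outside {{0,1,2}} at row "
            f"{ids.iloc[i]!r}, column {snps.columns[j]!r}"
        )
    return pd.DataFrame(arr.astype(np.int8), index=pd.Index(ids), columns=snps.columns)


def read_covariates(path) -> pd.DataFrame:
    """Read a real-valued covariate table (ID column then covariates)."""
    df = _read_table(path)
    idc = df.columns[0]
    data = df.set_index(idc)
    return data.apply(pd.to_numeric).astype(float)


def align_ids(*frames: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict all frames to their common IDs, preserving the first's order.

    Raises with the offending IDs when any frame lacks individuals that
    the others share.
    """
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no individual IDs shared across the input files")
    ordered = [i for i in frames[0].index if i in set(common)]
    out = []
    for f in frames:
        lost = set(f.index) - set(common)
        if lost:
            log.warning("dropping %d unmatched ID(s), e.g. %s", len(lost), sorted(lost)[:5])
        out.append(f.loc[ordered])
    return out
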