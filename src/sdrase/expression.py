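"""Bulk-expression computations: CPM, TMM factors, DEG screen, distances.

TMM (trimmed mean of M-values) between-library normalization is computed
from scratch: per library, M-values against a reference library are doubly
trimmed (30% on log-fold-change, 5% on absolute intensity) and averaged
with inverse-asymptotic-variance weights; factors are rescaled to a product
of one.  The differential-expression screen is a plain threshold rule —
CPM above a floor in at least one group and at least a fold-change between
group means — with no dispersion modeling.  Library dissimilarity is
1 - Spearman rank correlation over well-expressed genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class CountMatrix:
    """Gene x library integer counts with per-library metadata.

    ``counts`` is indexed by gene id with one column per library id;
    ``metadata`` (optional) is indexed by library id with columns such as
    sex and tissue.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate library ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.metadata is not None:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"libraries missing from metadata: {sorted(missing)}")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, metadata: pd.DataFrame | None = None
                 ) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts, metadata)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def cpm(
    counts: CountMatrix | pd.DataFrame,
    normalization_factors: Sequence[float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Counts per million, optionally scaled by normalization factors.

    value = count / (library_total * factor) * 1e6.  Without factors every
    column sums to exactly 1e6.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = df.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total libraries: {list(zero.index)}")
    if normalization_factors is not None:
        factors = np.asarray(normalization_factors, dtype=float)
        if factors.shape != (df.shape[1],):
            raise ValueError("one normalization factor per library required")
        totals = totals * factors
    return df.astype(float).div(totals, axis=1) * 1e6


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_logfc: float,
    trim_abs: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2^f)."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise ValueError("library shares no expressed genes with the reference")
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    log_ratio = np.log2(po / pr)  # M
    abs_expr = (np.log2(po) + np.log2(pr)) / 2.0  # A
    asym_var = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = len(log_ratio)
    lo_l = math.floor(n * trim_logfc) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_abs) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_ratio)
    rank_a = rankdata(abs_expr)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    w = 1.0 / asym_var[keep]
    f = float(np.sum(w * log_ratio[keep]) / np.sum(w))
    if not np.isfinite(f):
        return 1.0
    return 2.0 ** f


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_logfc: float = 0.3,
    trim_abs: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, product rescaled to 1.

    The reference library is the one whose upper-quartile count proportion
    is closest to the mean upper quartile across libraries.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    df = df.loc[df.sum(axis=1) > 0]  # all-zero genes are uninformative
    mat = df.to_numpy(dtype=float)
    lib_sizes = mat.sum(axis=0)
    if (lib_sizes == 0).any():
        raise ValueError("zero-total library")
    uq = np.array([np.quantile(mat[:, j] / lib_sizes[j], 0.75) for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair_factor(
                mat[:, j], mat[:, ref_idx], lib_sizes[j], lib_sizes[ref_idx],
                trim_logfc, trim_abs,
            )
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def deg_screen(
    counts: CountMatrix | pd.DataFrame,
    group_a_libs: Sequence[str],
    group_b_libs: Sequence[str],
    min_cpm: float = 8.0,
    min_fold: float = 2.0,
    pseudo_cpm: float = 0.5,
) -> pd.DataFrame:
    """Threshold DEG screen on TMM-adjusted CPM.

    A gene is reported when its mean CPM exceeds ``min_cpm`` in at least
    one group and the ratio of pseudo-counted group means is at least
    ``min_fold`` in either direction.  Returns gene_id-indexed columns
    mean_cpm_a, mean_cpm_b, fold_change (a over b), log2_fold_change.
    """
    group_a, group_b = list(group_a_libs), list(group_b_libs)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = (set(group_a) | set(group_b)) - set(df.columns)
    if missing:
        raise ValueError(f"unknown libraries: {sorted(missing)}")
    factors = tmm_factors(df[group_a + group_b])
    values = cpm(df[group_a + group_b], factors.loc[group_a + group_b])
    mean_a = values[group_a].mean(axis=1)
    mean_b = values[group_b].mean(axis=1)
    fold = (mean_a + pseudo_cpm) / (mean_b + pseudo_cpm)
    passes = ((mean_a > min_cpm) | (mean_b > min_cpm)) & (
        (fold >= min_fold) | (fold <= 1.0 / min_fold)
    )
    out = pd.DataFrame(
        {
            "mean_cpm_a": mean_a,
            "mean_cpm_b": mean_b,
            "fold_change": fold,
            "log2_fold_change": np.log2(fold),
        }
    )[passes]
    return out.sort_values("log2_fold_change", ascending=False)


def spearman_distance(
    counts: CountMatrix | pd.DataFrame,
    min_mean_cpm: float = 16.0,
    use_tmm: bool = True,
) -> pd.DataFrame:
    """Pairwise library dissimilarity 1 - rho over well-expressed genes.

    rho is the Spearman rank correlation between expression profiles
    restricted to genes whose average CPM across all libraries exceeds
    ``min_mean_cpm``; ties receive average ranks.  The result is symmetric
    with a zero diagonal and values in [0, 2].
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("need at least two libraries")
    factors = tmm_factors(df) if use_tmm else None
    values = cpm(df, factors)
    expressed = values[values.mean(axis=1) > min_mean_cpm]
    if expressed.shape[0] < 2:
        raise ValueError(
            f"only {expressed.shape[0]} genes pass mean CPM > {min_mean_cpm}"
        )
    ranks = expressed.rank(axis=0, method="average")
    constant = ranks.std(axis=0) == 0
    if constant.any():
        raise ValueError(
            "rank correlation undefined for constant expression profiles: "
            f"{list(ranks.columns[constant])}"
        )
    corr = np.corrcoef(ranks.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=df.columns, columns=df.columns)
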