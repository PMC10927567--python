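"""Differential protein-release statistics for digested vs undigested samples.

This module implements the Perseus-style analysis chain used to call which
proteins are released by region-specific RNase H digestion:

1. log2 transformation of intensities (missing stays missing),
2. a minimum-valid-values filter (default: >= 3 observed replicates in at
   least one group),
3. Gaussian downshift imputation of missing values — each sample column's
   missing cells are drawn from ``Normal(m - downshift*s, (width*s)^2)``
   where ``m``/``s`` are the column's observed mean/s.d. This models
   left-censored, missing-not-at-random low-abundance values,
4. an S0-modified two-sample test (SAM-style): the pooled-variance t
   statistic with an artificial within-groups standard deviation ``s0``
   added to the denominator, damping significance of small absolute
   differences,
5. permutation-based FDR: the observed |d| distribution is compared with
   |d| recomputed under sample-label permutations; q per protein is the
   monotonised ratio estimator,
6. the hyperbolic volcano significance boundary implied by an |d| cutoff,
7. PCA-based replicate QC and Benjamini-Hochberg adjustment helpers.

p-values for the S0 statistic use the Student t tail as an approximation;
significance decisions rest solely on the permutation q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ImputationError

__all__ = [
    "ImputeConfig",
    "TestConfig",
    "EnrichmentResult",
    "log2_transform",
    "filter_min_valid",
    "impute_gaussian_downshift",
    "two_sample_s0_test",
    "permutation_fdr",
    "significance_boundary",
    "pca_qc",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class ImputeConfig:
    """Gaussian downshift imputation parameters, in column-s.d. units."""

    downshift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downshift < 0:
            raise ConfigurationError("downshift must be >= 0")
        if self.width <= 0:
            raise ConfigurationError("width must be > 0")


@dataclass(frozen=True)
class TestConfig:
    """S0 test / permutation FDR parameters."""

    s0: float = 0.1
    alpha: float = 0.05
    n_perm: int = 250
    seed: int = 0
    min_valid: int = 3

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ConfigurationError("s0 must be >= 0")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")


@dataclass
class EnrichmentResult:
    """Per-protein differential-release statistics.

    ``frame`` has columns ``difference`` (mean log2 group A - group B),
    ``d_stat`` (the S0-modified statistic, the "t-score"), ``p`` (two-sided
    Student-t approximation), ``q`` (permutation FDR) and ``significant``.
    """

    frame: pd.DataFrame
    s0: float
    alpha: float
    df_resid: int
    n_perm_used: int
    exhaustive: bool
    d_threshold: float | None = field(default=None)

    def __post_init__(self) -> None:
        sig = self.frame["significant"]
        if sig.any():
            self.d_threshold = float(self.frame.loc[sig, "d_stat"].abs().min())

    @property
    def significant_proteins(self) -> pd.Index:
        return self.frame.index[self.frame["significant"]]


# ---------------------------------------------------------------------------
# Transform / filter / impute
# ---------------------------------------------------------------------------


def log2_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; missing stays missing; present values must be > 0."""
    values = table.to_numpy(dtype=float)
    present = ~np.isnan(values)
    if (values[present] <= 0).any():
        raise ValueError(
            "non-positive values present; zeros must already be encoded as missing"
        )
    return pd.DataFrame(np.log2(values, where=present, out=np.full_like(values, np.nan)),
                        index=table.index, columns=table.columns)


def _group_series(groups: pd.Series | pd.DataFrame, columns: pd.Index) -> pd.Series:
    if isinstance(groups, pd.DataFrame):
        groups = groups["group"]
    groups = groups.reindex(columns)
    if groups.isna().any():
        raise ConfigurationError(
            f"no group label for samples {list(groups.index[groups.isna()])}"
        )
    return groups


def filter_min_valid(table: pd.DataFrame, groups: pd.Series | pd.DataFrame,
                     min_valid: int = 3) -> pd.DataFrame:
    """Keep rows with >= min_valid observed values in at least one group."""
    groups = _group_series(groups, table.columns)
    sizes = groups.value_counts()
    if min_valid > sizes.max():
        raise ConfigurationError(
            f"min_valid={min_valid} exceeds the largest group size {sizes.max()}"
        )
    keep = pd.Series(False, index=table.index)
    for grp in sizes.index:
        cols = groups.index[groups == grp]
        keep |= table[cols].notna().sum(axis=1) >= min_valid
    return table.loc[keep]


def impute_gaussian_downshift(table: pd.DataFrame,
                              cfg: ImputeConfig = ImputeConfig()) -> pd.DataFrame:
    """Replace missing cells with draws from a downshifted Gaussian.

    Per column with observed mean ``m`` and s.d. ``s`` (ddof=1), missing
    cells are independent draws from ``Normal(m - downshift*s, (width*s)^2)``.
    Present cells are untouched; the result is deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    out = table.copy()
    for col in table.columns:
        column = table[col]
        present = column.dropna()
        n_missing = int(column.isna().sum())
        if n_missing == 0:
            continue
        if len(present) < 2:
            raise ImputationError(
                f"column {col!r} has {len(present)} observed values; "
                f"need >= 2 to estimate the imputation distribution"
            )
        m = float(present.mean())
        s = float(present.std(ddof=1))
        draws = rng.normal(m - cfg.downshift * s, cfg.width * s, size=n_missing)
        out.loc[column.isna(), col] = draws
    return out


# ---------------------------------------------------------------------------
# S0-modified two-sample test
# ---------------------------------------------------------------------------


def _s0_matrix(xa: np.ndarray, xb: np.ndarray, s0: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (difference, d_stat) for rows of two matrices."""
    na, nb = xa.shape[1], xb.shape[1]
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    return diff, d


def two_sample_s0_test(xa, xb, s0: float = 0.1) -> dict[str, float]:
    """S0-modified pooled-variance two-sample test for one protein.

    d = (mean(xa) - mean(xb)) / (se + s0) with se the pooled-variance
    standard error; p is the two-sided Student-t tail at d with
    ``len(xa) + len(xb) - 2`` degrees of freedom. With ``s0=0`` this is the
    classical Student two-sample t-test.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs >= 2 values (degrees of freedom)")
    diff, d = _s0_matrix(xa[None, :], xb[None, :], s0)
    df = xa.size + xb.size - 2
    p = 2.0 * stats.t.sf(abs(d[0]), df)
    return {"difference": float(diff[0]), "d_stat": float(d[0]), "p": float(min(p, 1.0))}


def _label_splits(n: int, na: int, n_perm: int, rng: np.random.Generator
                  ) -> tuple[list[tuple[int, ...]], bool]:
    """Group-A index sets to evaluate.

    All C(n, na) splits (identity included) when their count is <= n_perm;
    otherwise n_perm uniform draws from the non-identity splits.
    """
    total = comb(n, na)
    identity = tuple(range(na))
    if total <= n_perm:
        return [tuple(c) for c in combinations(range(n), na)], True
    splits: list[tuple[int, ...]] = []
    if total <= 200_000:
        pool = [tuple(c) for c in combinations(range(n), na) if tuple(c) != identity]
        idx = rng.choice(len(pool), size=n_perm, replace=n_perm > len(pool))
        splits = [pool[i] for i in idx]
    else:
        seen = 0
        while seen < n_perm:
            cand = tuple(sorted(rng.choice(n, size=na, replace=False).tolist()))
            if cand != identity:
                splits.append(cand)
                seen += 1
    return splits, False


def permutation_fdr(table: pd.DataFrame, groups: pd.Series | pd.DataFrame,
                    cfg: TestConfig = TestConfig(),
                    group_a: str | None = None,
                    group_b: str | None = None) -> EnrichmentResult:
    """Permutation-FDR S0 test over an imputation-complete table.

    The observed statistic d is computed per protein for the ``group_a`` vs
    ``group_b`` contrast; the same statistic is recomputed under label
    permutations (all distinct label splits when their number is at most
    ``cfg.n_perm``, else ``cfg.n_perm`` uniformly drawn non-identity
    splits). For each threshold c among the observed |d| values,

        FDR(c) = mean over permutations of #{|d_perm| >= c} / #{|d_obs| >= c}

    and a protein's q is the minimum FDR over thresholds at or below its
    |d| (monotonised, capped at 1). Significance means q <= cfg.alpha.
    """
    if table.isna().any().any():
        raise ValueError("table contains missing values; impute before testing")
    groups = _group_series(groups, table.columns)
    labels = [g for g in pd.unique(groups) ]
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ConfigurationError(
                f"need exactly two groups (or explicit group_a/group_b); "
                f"found {labels}"
            )
        group_a, group_b = labels[0], labels[1]
    cols_a = [c for c in table.columns if groups[c] == group_a]
    cols_b = [c for c in table.columns if groups[c] == group_b]
    na, nb = len(cols_a), len(cols_b)
    if na < 2 or nb < 2:
        raise ConfigurationError("each group needs >= 2 samples")

    data = table[cols_a + cols_b].to_numpy(dtype=float)
    n = na + nb
    diff, d_obs = _s0_matrix(data[:, :na], data[:, na:], cfg.s0)
    df = n - 2
    p = np.minimum(2.0 * stats.t.sf(np.abs(d_obs), df), 1.0)

    rng = np.random.default_rng(cfg.seed)
    splits, exhaustive = _label_splits(n, na, cfg.n_perm, rng)
    all_idx = np.arange(n)
    perm_abs = np.empty((len(splits), data.shape[0]))
    for k, split in enumerate(splits):
        ia = np.asarray(split)
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        _, d_perm = _s0_matrix(data[:, ia], data[:, ib], cfg.s0)
        perm_abs[k] = np.abs(d_perm)

    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")  # descending |d|
    sorted_abs = abs_obs[order]
    pooled = np.sort(perm_abs.ravel())
    # counts of permuted |d| >= c and observed |d| >= c at each threshold
    n_perm_ge = len(pooled) - np.searchsorted(pooled, sorted_abs, side="left")
    asc = sorted_abs[::-1]  # ascending observed |d|
    n_obs_ge = len(asc) - np.searchsorted(asc, sorted_abs, side="left")
    fdr = (n_perm_ge / len(splits)) / n_obs_ge
    # monotonise: q at a threshold is the best FDR at any lower threshold
    q_sorted = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    frame = pd.DataFrame(
        {
            "difference": diff,
            "d_stat": d_obs,
            "p": p,
            "q": q,
            "significant": q <= cfg.alpha,
        },
        index=table.index,
    )
    return EnrichmentResult(frame=frame, s0=cfg.s0, alpha=cfg.alpha,
                            df_resid=df, n_perm_used=len(splits),
                            exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# Volcano boundary
# ---------------------------------------------------------------------------


def significance_boundary(s0: float, d_cut: float, df: int,
                          diff_grid: np.ndarray | list[float]
                          ) -> pd.DataFrame:
    """Trace the volcano significance boundary implied by an |d| cutoff.

    For each |difference| x, a volcano point (x, p) implies a standard
    error ``se = x / t_p`` with ``t_p`` the two-sided t quantile of p, and
    hence ``d = x / (x / t_p + s0)``. The boundary is the minimal
    -log10 p at which d >= d_cut:

        t_p = x / (x / d_cut - s0),   requiring x > d_cut * s0.

    With ``s0 = 0`` the boundary is the horizontal line at the p of
    ``d_cut``. Points with |x| <= d_cut*s0 can never reach significance and
    get -log10 p = inf. The returned curve is symmetric in x.
    """
    if d_cut <= 0:
        raise ConfigurationError("d_cut must be > 0")
    grid = np.asarray(diff_grid, dtype=float)
    if grid.size == 0:
        return pd.DataFrame(columns=["difference", "neg_log10_p"])
    x = np.abs(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = x / d_cut - s0
        t_req = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), np.inf)
    p = 2.0 * stats.t.sf(t_req, df)
    neg = -np.log10(np.maximum(p, np.finfo(float).tiny))
    neg[~np.isfinite(t_req)] = np.inf
    curve = pd.DataFrame({"difference": np.sign(grid) * x, "neg_log10_p": neg})
    return curve


# ---------------------------------------------------------------------------
# PCA replicate QC
# ---------------------------------------------------------------------------


@dataclass
class PcaQcResult:
    coordinates: pd.DataFrame     # samples x (PC1, PC2)
    variance_fractions: np.ndarray
    flagged: list[str]


def pca_qc(table: pd.DataFrame, groups: pd.Series | pd.DataFrame,
           flag_factor: float = 3.0) -> PcaQcResult:
    """PCA of samples with a centroid-distance replicate-outlier rule.

    Principal components are computed on the centred sample x protein
    matrix. A replicate is flagged when its distance to its own group
    centroid in the (PC1, PC2) plane exceeds ``flag_factor`` times the
    median within-group centroid distance across all samples. Flags are
    advisory — nothing is removed automatically.
    """
    if table.shape[1] < 3:
        raise ConfigurationError("PCA QC needs at least 3 samples")
    if table.isna().any().any():
        raise ValueError("PCA requires an imputation-complete table")
    groups = _group_series(groups, table.columns)
    X = table.to_numpy(dtype=float).T  # samples x proteins
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    coords_full = pca.fit_transform(X - X.mean(axis=0))
    coords = pd.DataFrame(coords_full[:, :n_comp],
                          index=table.columns,
                          columns=[f"PC{i+1}" for i in range(n_comp)])
    dist = pd.Series(0.0, index=coords.index)
    for grp in pd.unique(groups):
        members = groups.index[groups == grp]
        centroid = coords.loc[members].mean(axis=0)
        dist[members] = np.sqrt(((coords.loc[members] - centroid) ** 2).sum(axis=1))
    med = float(dist.median())
    scale = float(np.abs(coords.to_numpy()).max(initial=1.0))
    atol = 1e-8 * max(scale, 1.0)  # exact-duplicate replicates stay unflagged
    flagged = list(dist.index[dist > flag_factor * med + atol])
    return PcaQcResult(coordinates=coords,
                       variance_fractions=pca.explained_variance_ratio_,
                       flagged=flagged)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
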