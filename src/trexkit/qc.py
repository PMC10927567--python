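"""Depletion-efficiency and specificity quality control.

Two QC branches accompany every RNase H targeting experiment:

* **qPCR depletion efficiency** — relative target RNA levels are estimated
  as 2^-dCT, with dCT the target Ct minus the mean housekeeping Ct, and
  depletion efficiency is 1 - treated/control.
* **Transcriptome-wide specificity** — from a TPM table of RNase H-treated
  vs control replicates (log2-transformed, min-valid filtered and
  downshift-imputed with the same operations as the proteomics chain), the
  per-transcript score is mean(control) - mean(treated): the displacement
  from the identity line of the group-mean scatter. A robust Gaussian null
  is fitted from the score distribution itself — sigma is the
  ``quantile``-level quantile of |score - median| divided by the matching
  normal quantile — and two-sided normal tail p-values are BH-adjusted.
  Transcripts with q <= alpha are reported as significant outliers, i.e.
  transcripts specifically depleted (or enriched) by the treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import stats_core as sc
from .errors import ConfigurationError

__all__ = [
    "SpecificityConfig",
    "relative_expression",
    "depletion_efficiency",
    "qpcr_relative_levels",
    "transcriptome_specificity",
    "rnaseq_specificity_pipeline",
]


@dataclass(frozen=True)
class SpecificityConfig:
    """Parameters of the quantile-based transcriptome outlier test."""

    quantile: float = 0.95
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.quantile < 1):
            raise ConfigurationError("quantile must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def relative_expression(ct_target: float, ct_housekeepers: Sequence[float]) -> float:
    """Relative RNA level 2^-(ct_target - mean(ct_housekeepers)).

    One extra cycle relative to the housekeeping mean halves the value.
    """
    hk = np.asarray(ct_housekeepers, dtype=float)
    if hk.size == 0:
        raise ConfigurationError("at least one housekeeping Ct is required")
    return float(2.0 ** (-(ct_target - hk.mean())))


def depletion_efficiency(level_treated: float, level_control: float) -> float:
    """Fraction of target removed: 1 - treated/control."""
    if level_control <= 0:
        raise ValueError("control level must be > 0")
    return 1.0 - level_treated / level_control


def qpcr_relative_levels(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-target 2^-dCT levels from a tidy Ct table.

    ``ct_table`` columns: sample_id, target, ct, housekeeping (boolean).
    Housekeeping Cts are averaged within each sample (arithmetic mean of
    cycles, i.e. geometric mean of expression).
    """
    required = {"sample_id", "target", "ct", "housekeeping"}
    if not required <= set(ct_table.columns):
        raise ConfigurationError(
            f"Ct table needs columns {sorted(required)}, got {list(ct_table.columns)}"
        )
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    rows = []
    for sample, sub in ct_table.groupby("sample_id"):
        hk = sub.loc[sub["housekeeping"].astype(bool), "ct"]
        if hk.empty:
            raise ConfigurationError(f"sample {sample!r} has no housekeeping target")
        for _, row in sub[~sub["housekeeping"].astype(bool)].iterrows():
            rows.append({
                "sample_id": sample,
                "target": row["target"],
                "relative_level": relative_expression(row["ct"], hk.to_numpy()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNA-seq specificity
# ---------------------------------------------------------------------------


def transcriptome_specificity(
    log_tpm: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    cfg: SpecificityConfig = SpecificityConfig(),
    *,
    group_control: str = "control",
    group_treated: str = "rnaseh",
) -> pd.DataFrame:
    """Quantile-based outlier test for RNase H depletion specificity.

    ``log_tpm`` must already be log2-transformed, min-valid-filtered and
    imputed (see :func:`rnaseq_specificity_pipeline` for the full chain).
    Returns per-transcript mean_control, mean_treated, score, p, q and the
    outlier flag. Positive scores mean depletion in the treated group.
    """
    groups = sc._group_series(groups, log_tpm.columns)
    cols_c = [c for c in log_tpm.columns if groups[c] == group_control]
    cols_t = [c for c in log_tpm.columns if groups[c] == group_treated]
    if len(cols_c) < 3 and len(cols_t) < 3:
        raise ConfigurationError(
            "the outlier test needs >= 3 replicates in at least one group "
            f"(got {len(cols_c)} control, {len(cols_t)} treated)"
        )
    if log_tpm.isna().any().any():
        raise ValueError("table contains missing values; impute first")
    mean_c = log_tpm[cols_c].mean(axis=1)
    mean_t = log_tpm[cols_t].mean(axis=1)
    score = mean_c - mean_t

    med = float(score.median())
    dev = (score - med).abs()
    sigma = float(np.quantile(dev, cfg.quantile)) / stats.norm.ppf(
        (1.0 + cfg.quantile) / 2.0)
    if sigma <= 0:
        raise ValueError("degenerate score distribution (zero spread)")
    z = (score - med) / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = sc.benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "score": score,
            "p": p,
            "q": q,
            "outlier": q <= cfg.alpha,
        },
        index=log_tpm.index,
    )
    return out


def rnaseq_specificity_pipeline(
    tpm: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    cfg: SpecificityConfig = SpecificityConfig(),
    impute_config: sc.ImputeConfig = sc.ImputeConfig(),
    min_valid: int = 3,
    **kwargs,
) -> pd.DataFrame:
    """log2 -> min-valid filter -> downshift imputation -> outlier test."""
    logged = sc.log2_transform(tpm)
    filtered = sc.filter_min_valid(logged, groups, min_valid=min_valid)
    imputed = sc.impute_gaussian_downshift(filtered, impute_config)
    return transcriptome_specificity(imputed, groups, cfg, **kwargs)
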