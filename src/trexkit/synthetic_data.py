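"""Synthetic TREX-like data with known ground truth.

The generators emulate the statistical structure the analysis chain
assumes, so every pipeline stage is testable without any deposited data:

* :func:`simulate_trex` — replicate log2-intensity tables for +RNase H vs
  -RNase H groups (plus total-lysate samples) with planted released
  proteins, intensity-dependent left-censored missingness and iBAQ columns
  derived from per-protein peptide counts;
* :func:`simulate_multiregion` — per-region tables sharing a background,
  with region-specific and multiregional planted binders;
* :func:`simulate_tpm` — log-normal TPM tables with planted depleted
  transcripts;
* :func:`simulate_qpcr` — Ct tables consistent with 2^-dCT quantification.

Every generator is a pure function of its config and seed: the same seed
yields byte-identical tables.

Default study conditions
------------------------
5 vs 5 biological replicates (3 and 4 vs 4 are common alternative designs
and are plain config changes), 1000 background and 50 released proteins,
baseline log2 intensity ~ Normal(26, 2.5), replicate noise s.d. 0.15 log2
units (~11% CV), release effect delta = 0.6 log2 units (4 replicate s.d.),
logistic left-censoring centred at the 15th intensity percentile. A
released protein's effect relates to its true bound fraction f through
delta = log2(1 + f): releasing a fraction f of the total amount on top of
the background level multiplies the +RNase H abundance by (1 + f).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quant_io import ProteinQuantTable

__all__ = [
    "TrexSimConfig",
    "GroundTruth",
    "simulate_trex",
    "simulate_multiregion",
    "simulate_tpm",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class TrexSimConfig:
    """Study conditions for a simulated TREX experiment."""

    n_background: int = 1000
    n_released: int = 50
    n_replicates: int = 5          # per +/- RNase H group
    n_total_replicates: int = 3
    base_mean: float = 26.0        # log2 intensity
    base_sd: float = 2.5
    delta: float = 0.6             # release effect, log2 units (4 x noise_sd)
    noise_sd: float = 0.15         # replicate noise, log2 units
    censor_quantile: float = 0.15  # missingness midpoint, intensity percentile
    censor_slope: float = 0.3      # logistic slope, log2 units; <=0 disables
    bound_fraction_range: tuple[float, float] | None = None
    peptide_lambda: float = 12.0   # peptide count ~ 1 + Poisson(lambda)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_released < 0 or self.n_background < 0:
            raise ConfigurationError("protein counts must be non-negative")
        if self.base_sd <= 0 or self.noise_sd <= 0:
            raise ConfigurationError("standard deviations must be > 0")
        if not (0 <= self.censor_quantile < 1):
            raise ConfigurationError("censor_quantile must lie in [0, 1)")
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates per group")
        if self.bound_fraction_range is not None:
            lo, hi = self.bound_fraction_range
            if not (0 < lo <= hi):
                raise ConfigurationError("bound fractions must be positive")


@dataclass
class GroundTruth:
    """What was planted: released proteins, regions, depleted transcripts."""

    released: pd.DataFrame = field(default_factory=pd.DataFrame)
    # ^ index protein_id; columns delta, bound_fraction (+ regions for
    #   multiregion simulations: a list per protein)
    depleted: dict[str, float] = field(default_factory=dict)
    levels: dict[str, float] = field(default_factory=dict)

    @property
    def released_ids(self) -> list[str]:
        return list(self.released.index)


def _protein_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _censor(values: np.ndarray, threshold: float, slope: float,
            rng: np.random.Generator) -> np.ndarray:
    """Left-censor log2 values: P(missing) = logistic((threshold - v)/slope)."""
    if slope <= 0:
        return values
    p_missing = 1.0 / (1.0 + np.exp((values - threshold) / slope))
    out = values.astype(float).copy()
    out[rng.random(values.shape) < p_missing] = np.nan
    return out


def simulate_trex(cfg: TrexSimConfig = TrexSimConfig()
                  ) -> tuple[ProteinQuantTable, GroundTruth]:
    """Simulate one TREX experiment: intensity + iBAQ table and truth.

    Per protein a baseline log2 intensity mu_i is drawn; each sample value
    is mu_i (+ delta_i in +RNase H samples of released proteins) plus
    replicate noise. Cells are set missing with logistic left-censoring on
    the log2 value; linear intensities are 2^value and iBAQ divides them by
    the protein's peptide count. Total-lysate samples carry the baseline
    without any release effect.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_background + cfg.n_released
    ids = _protein_ids(n)
    mu = rng.normal(cfg.base_mean, cfg.base_sd, size=n)
    peptide_counts = 1 + rng.poisson(cfg.peptide_lambda, size=n)

    released_idx = rng.choice(n, size=cfg.n_released, replace=False) \
        if cfg.n_released else np.array([], dtype=int)
    delta = np.zeros(n)
    if cfg.n_released:
        if cfg.bound_fraction_range is not None:
            lo, hi = cfg.bound_fraction_range
            fractions = rng.uniform(lo, hi, size=cfg.n_released)
            delta[released_idx] = np.log2(1.0 + fractions)
        else:
            delta[released_idx] = cfg.delta

    cols, groups, reps = [], [], []
    blocks = []
    for r in range(1, cfg.n_replicates + 1):
        cols.append(f"plus_{r}")
        groups.append("plus_rnaseh")
        reps.append(r)
        blocks.append(mu + delta + rng.normal(0, cfg.noise_sd, size=n))
    for r in range(1, cfg.n_replicates + 1):
        cols.append(f"minus_{r}")
        groups.append("minus_rnaseh")
        reps.append(r)
        blocks.append(mu + rng.normal(0, cfg.noise_sd, size=n))
    for r in range(1, cfg.n_total_replicates + 1):
        cols.append(f"total_{r}")
        groups.append("total")
        reps.append(r)
        blocks.append(mu + rng.normal(0, cfg.noise_sd, size=n))
    values = np.column_stack(blocks)

    threshold = float(np.quantile(values, cfg.censor_quantile)) \
        if cfg.censor_quantile > 0 else -np.inf
    censored = _censor(values, threshold, cfg.censor_slope, rng)

    intensity = pd.DataFrame(2.0 ** censored, index=ids, columns=cols)
    ibaq = intensity.div(peptide_counts, axis=0)
    samples = pd.DataFrame({"group": groups, "replicate": reps},
                           index=pd.Index(cols, name="sample_id"))
    table = ProteinQuantTable(intensity=intensity, ibaq=ibaq, samples=samples)

    released = pd.DataFrame(
        {
            "delta": delta[released_idx],
            "bound_fraction": 2.0 ** delta[released_idx] - 1.0,
        },
        index=pd.Index([ids[i] for i in released_idx], name="protein_id"),
    ).sort_index()
    return table, GroundTruth(released=released)


def simulate_multiregion(
    cfg: TrexSimConfig = TrexSimConfig(),
    *,
    n_regions: int = 8,
    fraction_multiregional: float = 0.05,
    multiregion_span: tuple[int, int] = (3, 5),
    region_names: Sequence[str] | None = None,
) -> tuple[dict[str, ProteinQuantTable], GroundTruth]:
    """Simulate per-region TREX tables with planted binder classes.

    Region-specific binders are released in exactly one region's +RNase H
    group; multiregional binders in ``multiregion_span`` (>= 3) randomly
    chosen regions, each with an independent delta jittered around
    ``cfg.delta``. All regions share the background proteins (same
    baselines, independent noise).
    """
    if n_regions < 2:
        raise ConfigurationError("need >= 2 regions")
    if not (0 <= fraction_multiregional <= 1):
        raise ConfigurationError("fraction_multiregional must lie in [0, 1]")
    if multiregion_span[0] < 3:
        raise ConfigurationError("multiregional binders span >= 3 regions")
    regions = list(region_names) if region_names is not None \
        else [f"region_{i+1}" for i in range(n_regions)]
    if len(regions) != n_regions or len(set(regions)) != n_regions:
        raise ConfigurationError("region names must be unique, one per region")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_background + cfg.n_released
    ids = _protein_ids(n)
    mu = rng.normal(cfg.base_mean, cfg.base_sd, size=n)
    peptide_counts = 1 + rng.poisson(cfg.peptide_lambda, size=n)

    released_idx = rng.choice(n, size=cfg.n_released, replace=False)
    n_multi = int(round(cfg.n_released * fraction_multiregional))
    multi_idx = released_idx[:n_multi]
    single_idx = released_idx[n_multi:]

    membership: dict[int, list[str]] = {}
    for i in single_idx:
        membership[int(i)] = [regions[rng.integers(n_regions)]]
    lo, hi = multiregion_span
    hi = min(hi, n_regions)
    for i in multi_idx:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(n_regions, size=k, replace=False)
        membership[int(i)] = [regions[j] for j in sorted(chosen)]

    tables: dict[str, ProteinQuantTable] = {}
    for region in regions:
        delta = np.zeros(n)
        for i, regs in membership.items():
            if region in regs:
                delta[i] = cfg.delta * rng.uniform(0.8, 1.2)
        cols, groups, reps, blocks = [], [], [], []
        for r in range(1, cfg.n_replicates + 1):
            cols.append(f"{region}_plus_{r}")
            groups.append("plus_rnaseh")
            reps.append(r)
            blocks.append(mu + delta + rng.normal(0, cfg.noise_sd, size=n))
        for r in range(1, cfg.n_replicates + 1):
            cols.append(f"{region}_minus_{r}")
            groups.append("minus_rnaseh")
            reps.append(r)
            blocks.append(mu + rng.normal(0, cfg.noise_sd, size=n))
        values = np.column_stack(blocks)
        threshold = float(np.quantile(values, cfg.censor_quantile)) \
            if cfg.censor_quantile > 0 else -np.inf
        censored = _censor(values, threshold, cfg.censor_slope, rng)
        intensity = pd.DataFrame(2.0 ** censored, index=ids, columns=cols)
        samples = pd.DataFrame({"group": groups, "replicate": reps},
                               index=pd.Index(cols, name="sample_id"))
        tables[region] = ProteinQuantTable(
            intensity=intensity,
            ibaq=intensity.div(peptide_counts, axis=0),
            samples=samples,
        )

    released = pd.DataFrame(
        {
            "regions": [membership[int(i)] for i in released_idx],
            "multiregional": [len(membership[int(i)]) >= 3 for i in released_idx],
        },
        index=pd.Index([ids[i] for i in released_idx], name="protein_id"),
    ).sort_index()
    return tables, GroundTruth(released=released)


def simulate_tpm(
    n_transcripts: int = 5000,
    depleted: Mapping[str, float] | None = None,
    *,
    n_replicates: int = 3,
    log_mean: float = 4.0,
    log_sd: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a TPM table for the RNase H specificity test.

    Transcript abundances are log-normal; in the treated group the planted
    transcripts are divided by their fold change (folds >= 1). Returns
    (tpm table, group labels, truth). Transcript ids are T00001... and
    depleted ids may name any of them.
    """
    depleted = dict(depleted or {})
    if any(f < 1 for f in depleted.values()):
        raise ConfigurationError("depletion fold changes must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"T{i:05d}" for i in range(1, n_transcripts + 1)]
    unknown = set(depleted) - set(ids)
    if unknown:
        raise ConfigurationError(f"unknown depleted transcript ids {sorted(unknown)}")
    base = rng.normal(log_mean, log_sd, size=n_transcripts)
    shift = np.zeros(n_transcripts)
    for tid, fold in depleted.items():
        shift[ids.index(tid)] = np.log2(fold)

    cols, groups, blocks = [], [], []
    for r in range(1, n_replicates + 1):
        cols.append(f"control_{r}")
        groups.append("control")
        blocks.append(base + rng.normal(0, noise_sd, size=n_transcripts))
    for r in range(1, n_replicates + 1):
        cols.append(f"rnaseh_{r}")
        groups.append("rnaseh")
        blocks.append(base - shift + rng.normal(0, noise_sd, size=n_transcripts))
    tpm = pd.DataFrame(2.0 ** np.column_stack(blocks), index=ids, columns=cols)
    labels = pd.Series(groups, index=cols, name="group")
    return tpm, labels, GroundTruth(depleted=depleted)


def simulate_qpcr(
    levels: Mapping[str, float],
    *,
    housekeeping_ct: Mapping[str, float] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_prefix: str = "sample",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a tidy qPCR Ct table from true relative expression levels.

    ct_target = mean(housekeeping Ct) - log2(level) + Normal(0, noise_sd),
    the inverse of the 2^-dCT estimator, so at zero noise
    :func:`trexkit.qc.relative_expression` recovers the levels exactly.
    """
    if housekeeping_ct is None:
        housekeeping_ct = {"GAPDH": 18.0, "RPS18": 20.0}
    if any(lv <= 0 for lv in levels.values()):
        raise ConfigurationError("relative levels must be > 0")
    rng = np.random.default_rng(seed)
    hk_mean = float(np.mean(list(housekeeping_ct.values())))
    rows = []
    for r in range(1, n_replicates + 1):
        sample = f"{sample_prefix}_{r}"
        for hk, ct in housekeeping_ct.items():
            rows.append({"sample_id": sample, "target": hk,
                         "ct": ct, "housekeeping": True})
        for target, level in levels.items():
            ct = hk_mean - np.log2(level) + rng.normal(0, noise_sd)
            rows.append({"sample_id": sample, "target": target,
                         "ct": float(ct), "housekeeping": False})
    return pd.DataFrame(rows), GroundTruth(levels=dict(levels))


def null_config(cfg: TrexSimConfig = TrexSimConfig(), seed: int | None = None
                ) -> TrexSimConfig:
    """The same conditions with no released proteins (null calibration)."""
    kwargs = {"n_released": 0}
    if seed is not None:
        kwargs["seed"] = seed
    return replace(cfg, **kwargs)
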