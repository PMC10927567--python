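"""iBAQ-based estimation of relative RNA-binding affinity.

Because RNase H digestion releases bound proteins near-stoichiometrically,
the ratio of a protein's released abundance to its total cellular abundance
estimates its relative affinity for the targeted RNA region:

    Ka = [RNA bound] / [Total] = iBAQ_TREX / iBAQ_total

where iBAQ_TREX is the mean iBAQ over +RNase H samples minus the mean over
-RNase H (background-release) samples, and iBAQ_total is the mean iBAQ in
total-lysate samples.

Missing-value policy (absence of evidence for release): a missing iBAQ in a
-RNase H control is treated as 0 before averaging, since it indicates no
detectable background release; a protein with no observed +RNase H or total
iBAQ has an undefined Ka. Non-positive iBAQ_TREX also leaves Ka undefined —
the quantity models released material and a negative release estimate is
noise. Undefined records are reported but excluded from ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quant_io import ProteinQuantTable

__all__ = ["estimate_affinity"]


def estimate_affinity(
    quant: ProteinQuantTable,
    *,
    group_plus: str = "plus_rnaseh",
    group_minus: str = "minus_rnaseh",
    group_total: str = "total",
) -> pd.DataFrame:
    """Estimate each protein's relative affinity Ka for the target RNA.

    Returns a DataFrame with columns ``ibaq_trex``, ``ibaq_total``, ``ka``
    and ``rank`` (dense, descending in Ka, NaN for undefined records),
    sorted by rank with undefined records last.
    """
    if quant.ibaq is None:
        raise ConfigurationError("quantification table carries no iBAQ matrix")
    cols_plus = quant.group_samples(group_plus)
    cols_minus = quant.group_samples(group_minus)
    cols_total = quant.group_samples(group_total)
    if not cols_total:
        raise ConfigurationError(f"no samples in total group {group_total!r}")
    if not cols_plus:
        raise ConfigurationError(f"no samples in group {group_plus!r}")

    ibaq = quant.ibaq
    plus = ibaq[cols_plus].mean(axis=1)               # mean over observed
    minus = ibaq[cols_minus].fillna(0.0).mean(axis=1) if cols_minus \
        else pd.Series(0.0, index=ibaq.index)
    total = ibaq[cols_total].mean(axis=1)

    ibaq_trex = plus - minus
    ibaq_trex[plus.isna()] = np.nan                   # nothing released observed
    ka = ibaq_trex / total
    undefined = ibaq_trex.isna() | (ibaq_trex <= 0) | total.isna() | (total <= 0)
    ka[undefined] = np.nan

    out = pd.DataFrame({
        "ibaq_trex": ibaq_trex,
        "ibaq_total": total,
        "ka": ka,
    })
    out["rank"] = out["ka"].rank(method="dense", ascending=False)
    out = out.sort_values(["rank", "ka"], na_position="last")
    return out
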