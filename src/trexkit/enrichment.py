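"""High-level differential-release model: filter, impute, test, report.

:class:`ReleaseEnrichment` bundles the full digested-vs-undigested analysis
chain behind a statsmodels-style interface: build the model from a
:class:`~trexkit.quant_io.ProteinQuantTable` (or directly from a MaxQuant
proteinGroups file plus a sample sheet), call :meth:`ReleaseEnrichment.fit`,
and receive a :class:`ReleaseEnrichmentResults` carrying per-protein
estimates, permutation q-values, replicate QC diagnostics and plotting /
export helpers.

Example
-------
>>> from trexkit import synthetic_data as sim
>>> table, truth = sim.simulate_trex(sim.TrexSimConfig(seed=7))
>>> res = ReleaseEnrichment(table).fit()
>>> hits = res.significant_hits
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats_core as sc
from .errors import ConfigurationError
from .quant_io import ProteinQuantTable, parse_protein_groups, read_sample_sheet

__all__ = ["ReleaseEnrichment", "ReleaseEnrichmentResults"]


class ReleaseEnrichment:
    """Model for protein release in +RNase H vs -RNase H TREX samples.

    Parameters
    ----------
    table
        A :class:`ProteinQuantTable` or a raw proteins x samples intensity
        DataFrame (linear scale, NaN for missing) plus a ``samples`` sheet.
    impute_config, test_config
        Imputation and testing parameters; defaults follow the standard
        Perseus settings (downshift 1.8 s.d., width 0.3 s.d., S0 = 0.1,
        FDR 0.05, min 3 valid values in at least one group).
    group_a, group_b
        The contrasted groups; the difference reported is A minus B.
    """

    def __init__(
        self,
        table: ProteinQuantTable | pd.DataFrame,
        samples: pd.DataFrame | None = None,
        *,
        impute_config: sc.ImputeConfig = sc.ImputeConfig(),
        test_config: sc.TestConfig = sc.TestConfig(),
        group_a: str = "plus_rnaseh",
        group_b: str = "minus_rnaseh",
    ) -> None:
        if isinstance(table, ProteinQuantTable):
            self.intensity = table.intensity
            self.samples = table.samples
            self.quant = table
        else:
            if samples is None:
                raise ConfigurationError(
                    "a sample sheet is required with a plain DataFrame"
                )
            self.intensity = table
            self.samples = samples
            self.quant = None
        self.impute_config = impute_config
        self.test_config = test_config
        self.group_a = group_a
        self.group_b = group_b
        groups = self.samples["group"]
        for grp in (group_a, group_b):
            if (groups == grp).sum() < 2:
                raise ConfigurationError(
                    f"group {grp!r} has fewer than 2 samples"
                )

    @classmethod
    def from_protein_groups(
        cls, path: str | Path, sample_sheet: str | Path | pd.DataFrame, **kwargs
    ) -> "ReleaseEnrichment":
        """Build the model directly from a MaxQuant proteinGroups file."""
        if not isinstance(sample_sheet, pd.DataFrame):
            sample_sheet = read_sample_sheet(sample_sheet)
        quant = parse_protein_groups(path, sample_sheet)
        return cls(quant, **kwargs)

    def fit(self) -> "ReleaseEnrichmentResults":
        """Run the full chain and return the results object."""
        cols = [c for c in self.intensity.columns
                if self.samples.loc[c, "group"] in (self.group_a, self.group_b)]
        sub = self.intensity[cols]
        groups = self.samples.loc[cols, "group"]
        logged = sc.log2_transform(sub)
        filtered = sc.filter_min_valid(logged, groups,
                                       min_valid=self.test_config.min_valid)
        imputed = sc.impute_gaussian_downshift(filtered, self.impute_config)
        result = sc.permutation_fdr(imputed, groups, self.test_config,
                                    group_a=self.group_a, group_b=self.group_b)
        pca = sc.pca_qc(imputed, groups) if len(cols) >= 3 else None
        return ReleaseEnrichmentResults(self, result, imputed, filtered, pca)


@dataclass
class ReleaseEnrichmentResults:
    """Fitted differential-release results.

    ``frame`` columns: difference (log2 A - B), d_stat, p, q, significant.
    """

    model: ReleaseEnrichment
    enrichment: sc.EnrichmentResult
    imputed: pd.DataFrame
    filtered: pd.DataFrame
    pca: sc.PcaQcResult | None

    @property
    def frame(self) -> pd.DataFrame:
        return self.enrichment.frame

    @property
    def significant_hits(self) -> pd.Index:
        return self.enrichment.significant_proteins

    # -- derived views ------------------------------------------------------

    def volcano_coordinates(self) -> pd.DataFrame:
        """(difference, -log10 p, significant) per protein, volcano axes."""
        f = self.frame
        return pd.DataFrame(
            {
                "difference": f["difference"],
                "neg_log10_p": -np.log10(np.maximum(f["p"], np.finfo(float).tiny)),
                "significant": f["significant"],
            },
            index=f.index,
        )

    def significance_curve(self, n_points: int = 200) -> pd.DataFrame:
        """The volcano boundary implied by the fitted |d| threshold."""
        d_cut = self.enrichment.d_threshold
        if d_cut is None:
            return pd.DataFrame(columns=["difference", "neg_log10_p"])
        xmax = float(self.frame["difference"].abs().max()) * 1.05
        grid = np.linspace(-xmax, xmax, n_points)
        return sc.significance_boundary(
            self.enrichment.s0, d_cut, self.enrichment.df_resid, grid)

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        e = self.enrichment
        n_sig = int(self.frame["significant"].sum())
        up = int((self.frame["significant"] & (self.frame["difference"] > 0)).sum())
        lines = [
            "Release enrichment (S0-modified two-sample test, permutation FDR)",
            "=" * 68,
            f"contrast:            {self.model.group_a} - {self.model.group_b}",
            f"proteins tested:     {len(self.frame)}",
            f"S0:                  {e.s0}",
            f"FDR threshold:       {e.alpha}",
            f"permutations:        {e.n_perm_used}"
            f" ({'exhaustive' if e.exhaustive else 'sampled'})",
            f"significant:         {n_sig} ({up} released, {n_sig - up} depleted)",
        ]
        if e.d_threshold is not None:
            lines.append(f"|d| at boundary:     {e.d_threshold:.3f}")
        if self.pca is not None and self.pca.flagged:
            lines.append(f"flagged replicates:  {', '.join(self.pca.flagged)}")
        top = (self.frame[self.frame["significant"]]
               .sort_values("d_stat", ascending=False).head(10))
        if len(top):
            lines += ["", "top released proteins:",
                      top.to_string(float_format=lambda v: f"{v:.3g}")]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Volcano plot with the significance boundary, returns the Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        coords = self.volcano_coordinates()
        sig = coords["significant"]
        ax.scatter(coords.loc[~sig, "difference"], coords.loc[~sig, "neg_log10_p"],
                   s=8, c="0.6", label="n.s.")
        ax.scatter(coords.loc[sig, "difference"], coords.loc[sig, "neg_log10_p"],
                   s=10, c="crimson", label="significant")
        curve = self.significance_curve()
        if len(curve):
            for sign in (-1, 1):
                side = curve[np.sign(curve["difference"]) == sign]
                finite = side[np.isfinite(side["neg_log10_p"])]
                ax.plot(finite["difference"], finite["neg_log10_p"],
                        c="k", lw=1, ls="--")
        ax.set_xlabel("log2 difference (+RNase H - -RNase H)")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax

    # -- export -------------------------------------------------------------

    def to_tsv(self, prefix: str | Path) -> None:
        """Write result, volcano-coordinate, boundary and QC tables."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        base = prefix.parent / prefix.name
        self.frame.to_csv(f"{base}.enrichment.tsv", sep="\t")
        self.volcano_coordinates().to_csv(f"{base}.volcano.tsv", sep="\t")
        self.significance_curve().to_csv(f"{base}.boundary.tsv", sep="\t",
                                         index=False)
        log: dict = {
            "group_a": self.model.group_a,
            "group_b": self.model.group_b,
            "s0": self.enrichment.s0,
            "alpha": self.enrichment.alpha,
            "n_perm_used": self.enrichment.n_perm_used,
            "exhaustive": self.enrichment.exhaustive,
            "n_significant": int(self.frame["significant"].sum()),
        }
        if self.pca is not None:
            self.pca.coordinates.to_csv(f"{base}.pca.tsv", sep="\t")
            log["pca_flagged"] = self.pca.flagged
            log["pca_variance_fractions"] = [
                float(v) for v in self.pca.variance_fractions[:2]]
        with open(f"{base}.log.json", "w") as fh:
            json.dump(log, fh, indent=2)
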