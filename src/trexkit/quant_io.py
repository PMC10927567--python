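"""Parsing and validation of MaxQuant-style protein quantification tables.

The central container is :class:`ProteinQuantTable`: a proteins x samples
intensity matrix (and an optional iBAQ matrix of the same shape) with an
explicit missingness encoding (NaN) and a sample sheet assigning each sample
to a group (``plus_rnaseh``, ``minus_rnaseh`` or ``total``) and a replicate
number. Zeros in MaxQuant output mean "not quantified", so they are
converted to missing on parse; rows flagged as reverse-database hits,
potential contaminants or site-only identifications are dropped by default.

iBAQ (intensity-based absolute quantification) divides a protein's summed
peptide intensity by its number of theoretically observable tryptic
peptides, giving a within-sample proxy for protein copy number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = [
    "ProteinQuantTable",
    "DigestParams",
    "read_sample_sheet",
    "parse_protein_groups",
    "count_tryptic_peptides",
    "compute_ibaq",
    "write_quant_table",
    "read_quant_table",
]

GROUPS = ("plus_rnaseh", "minus_rnaseh", "total")

_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")
_AA = set("ACDEFGHIKLMNPQRSTVWYUBXZ")


@dataclass
class ProteinQuantTable:
    """Proteins x samples quantification matrix with group annotations.

    Attributes
    ----------
    intensity : pandas.DataFrame
        Non-negative intensities, proteins as index, sample ids as columns;
        missing values are NaN (never 0).
    ibaq : pandas.DataFrame or None
        iBAQ matrix with identical shape/labels, or None if unavailable.
    samples : pandas.DataFrame
        Indexed by sample id with columns ``group`` and ``replicate``.
    gene_names : pandas.Series
        Optional gene symbol per protein (empty strings if unknown).
    """

    intensity: pd.DataFrame
    samples: pd.DataFrame
    ibaq: pd.DataFrame | None = None
    gene_names: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_names is None:
            self.gene_names = pd.Series("", index=self.intensity.index)
        self.validate()

    def validate(self) -> None:
        inten = self.intensity
        if (inten.to_numpy() < 0).any():
            raise ValueError("negative intensity values")
        if (inten.to_numpy() == 0).any():
            raise ValueError("zero intensities must be encoded as missing (NaN)")
        if self.ibaq is not None:
            if not self.ibaq.index.equals(inten.index) \
                    or not self.ibaq.columns.equals(inten.columns):
                raise ValueError("iBAQ matrix labels differ from intensity matrix")
        missing_cols = {"group", "replicate"} - set(self.samples.columns)
        if missing_cols:
            raise FormatError(f"sample sheet lacks columns {sorted(missing_cols)}")
        unknown = set(self.samples["group"]) - set(GROUPS)
        if unknown:
            raise FormatError(
                f"unknown group labels {sorted(unknown)}; expected one of {GROUPS}"
            )
        extra = set(inten.columns) - set(self.samples.index)
        if extra:
            raise FormatError(f"samples missing from sheet: {sorted(extra)}")
        for grp, sub in self.samples.groupby("group"):
            if sub["replicate"].duplicated().any():
                raise FormatError(f"duplicate replicate ids within group {grp!r}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensity.index

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to a group, ordered by replicate."""
        sub = self.samples[self.samples["group"] == group]
        sub = sub.sort_values("replicate")
        return [s for s in sub.index if s in self.intensity.columns]

    def missing_mask(self) -> pd.DataFrame:
        return self.intensity.isna()


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV with columns sample_id, group, replicate."""
    sheet = pd.read_csv(path)
    required = {"sample_id", "group", "replicate"}
    if not required <= set(sheet.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(required)}, "
            f"got {list(sheet.columns)}"
        )
    sheet = sheet.set_index("sample_id")
    sheet["replicate"] = sheet["replicate"].astype(int)
    return sheet


def parse_protein_groups(
    path: str | Path,
    sample_sheet: pd.DataFrame | str | Path,
    *,
    intensity_prefix: str = "LFQ intensity ",
    ibaq_prefix: str = "iBAQ ",
    filter_flagged: bool = True,
) -> ProteinQuantTable:
    """Parse a MaxQuant proteinGroups.txt-style tab-delimited table.

    Intensity columns are located by prefix match against the sample ids of
    the sample sheet. Zeros become missing; flagged rows (reverse /
    contaminant / site-only, marked '+') are removed unless
    ``filter_flagged=False``; duplicate protein ids keep the first row with
    a warning.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    id_col = next(
        (c for c in ("Protein IDs", "Majority protein IDs", "Protein ID")
         if c in raw.columns), None)
    if id_col is None:
        raise FormatError("no protein id column found (expected 'Protein IDs')")

    sample_ids = list(sample_sheet.index)
    int_cols = {s: intensity_prefix + s for s in sample_ids
                if intensity_prefix + s in raw.columns}
    if not int_cols:
        raise FormatError(
            f"no intensity columns with prefix {intensity_prefix!r} matching "
            f"the sample sheet"
        )
    absent = [s for s in sample_ids if s not in int_cols]
    if absent:
        raise FormatError(f"intensity columns missing for samples {absent}")
    ibaq_cols = {s: ibaq_prefix + s for s in sample_ids
                 if ibaq_prefix + s in raw.columns}

    if filter_flagged:
        for col in _FLAG_COLUMNS:
            if col in raw.columns:
                raw = raw[raw[col].fillna("") != "+"]

    if raw[id_col].duplicated().any():
        dupes = raw.loc[raw[id_col].duplicated(), id_col].unique()
        warnings.warn(
            f"duplicate protein ids {list(dupes)[:5]}...; keeping first occurrence",
            stacklevel=2,
        )
        raw = raw[~raw[id_col].duplicated()]
    raw = raw.set_index(id_col)
    raw.index.name = "protein_id"

    def numeric(colmap: dict[str, str]) -> pd.DataFrame:
        mat = raw[[colmap[s] for s in sample_ids if s in colmap]].apply(
            pd.to_numeric, errors="coerce")
        mat.columns = [s for s in sample_ids if s in colmap]
        return mat.where(mat != 0)  # zero means not quantified

    intensity = numeric(int_cols)
    ibaq = numeric(ibaq_cols) if len(ibaq_cols) == len(sample_ids) else None
    gene_names = (raw["Gene names"].fillna("") if "Gene names" in raw.columns
                  else pd.Series("", index=raw.index))
    return ProteinQuantTable(
        intensity=intensity, ibaq=ibaq, samples=sample_sheet,
        gene_names=gene_names,
    )


# ---------------------------------------------------------------------------
# iBAQ
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigestParams:
    """Peptide length bounds (aa) for the theoretical tryptic digest."""

    min_len: int = 6
    max_len: int = 30

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ConfigurationError(
                f"need 1 <= min_len <= max_len, got ({self.min_len}, {self.max_len})"
            )


def count_tryptic_peptides(protein_seq: str,
                           params: DigestParams = DigestParams()) -> int:
    """Count theoretically observable tryptic peptides of a protein.

    Cleaves C-terminal to K or R except when the next residue is P (the
    canonical trypsin rule, no missed cleavages) and counts the peptides
    whose length falls within ``[min_len, max_len]``.
    """
    seq = protein_seq.upper().strip("*")
    if not seq:
        return 0
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"invalid amino-acid characters: {sorted(bad)!r}")
    peptides = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            peptides.append(seq[start:i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return sum(params.min_len <= len(p) <= params.max_len for p in peptides)


def compute_ibaq(total_intensity: float, peptide_count: int) -> float:
    """iBAQ = summed intensity / number of theoretically observable peptides.

    Returns NaN when the peptide count is zero or the intensity is missing.
    """
    if total_intensity is None or np.isnan(total_intensity):
        return float("nan")
    if total_intensity < 0:
        raise ValueError(f"negative intensity {total_intensity}")
    if peptide_count <= 0:
        return float("nan")
    return total_intensity / peptide_count


# ---------------------------------------------------------------------------
# Round-trip I/O
# ---------------------------------------------------------------------------


def _p(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


def write_quant_table(table: ProteinQuantTable, prefix: str | Path) -> None:
    """Write a normalized TSV representation (values, iBAQ, sample sheet).

    ``prefix`` is extended with ``.intensity.tsv``, ``.ibaq.tsv`` (when
    present) and ``.samples.csv``. Missing cells are written as empty
    fields; floats use repr precision so a round trip is bit-exact.
    """
    prefix = Path(prefix)
    table.intensity.to_csv(_p(prefix, ".intensity.tsv"), sep="\t")
    if table.ibaq is not None:
        table.ibaq.to_csv(_p(prefix, ".ibaq.tsv"), sep="\t")
    sheet = table.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(_p(prefix, ".samples.csv"))


def read_quant_table(prefix: str | Path) -> ProteinQuantTable:
    """Inverse of :func:`write_quant_table`."""
    prefix = Path(prefix)
    intensity = pd.read_csv(_p(prefix, ".intensity.tsv"), sep="\t",
                            index_col=0)
    ibaq_path = _p(prefix, ".ibaq.tsv")
    ibaq = pd.read_csv(ibaq_path, sep="\t", index_col=0) if ibaq_path.exists() \
        else None
    samples = pd.read_csv(_p(prefix, ".samples.csv"),
                          index_col="sample_id")
    return ProteinQuantTable(intensity=intensity, ibaq=ibaq, samples=samples)
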