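"""Over-representation analysis of hit lists against annotation sets.

Each annotation set (e.g. a GO category or a curated ribosome-biogenesis
factor list, read from GMT records) is tested for enrichment among the
significant hits by a two-sided Fisher's exact test on the 2x2 table

    a = |hits & set|     b = |hits - set|
    c = |set - hits|     d = |universe - hits - set|

with the universe being all quantified proteins of the experiment.
p-values are Benjamini-Hochberg adjusted across sets; a set is enriched
when q <= alpha and the odds ratio exceeds 1. The default FDR cut-off is
0.02 (0.05 is also in common use for the same analysis; both are exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import fisher_exact

from .errors import ConfigurationError, FormatError
from .stats_core import benjamini_hochberg

__all__ = [
    "AnnotationSets",
    "read_gmt",
    "fisher_test_counts",
    "fisher_enrichment",
]


@dataclass
class AnnotationSets:
    """Named protein sets restricted to a quantified universe."""

    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ConfigurationError("universe is empty")
        restricted = {}
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"annotation set {name!r} is empty")
            inside = set(members) & self.universe
            self.dropped[name] = len(members) - len(inside)
            if inside:
                restricted[name] = inside
        self.sets = restricted


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse a GMT file: one set per line, tab-delimited name/desc/members."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">= 1 member"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return sets, descriptions


def fisher_test_counts(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on counts (a, b, c, d).

    Returns (odds_ratio, p). The two-sided p sums all tables with the given
    margins whose probability does not exceed the observed one (the
    standard R/scipy convention).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def fisher_enrichment(
    hits: Iterable[str],
    annotations: AnnotationSets | Mapping[str, Iterable[str]],
    *,
    universe: Iterable[str] | None = None,
    alpha: float = 0.02,
) -> pd.DataFrame:
    """Fisher over-representation of ``hits`` in each annotation set.

    Returns one row per set: counts a/b/c/d, odds_ratio, p, q and the
    ``enriched`` flag (q <= alpha and odds_ratio > 1), sorted by p.
    """
    if not isinstance(annotations, AnnotationSets):
        if universe is None:
            raise ConfigurationError(
                "universe is required when passing a plain set mapping"
            )
        annotations = AnnotationSets(
            sets={k: set(v) for k, v in annotations.items()},
            universe=set(universe),
        )
    hit_set = set(hits)
    if not hit_set:
        raise ConfigurationError("hit list is empty")
    stray = hit_set - annotations.universe
    if stray:
        raise ConfigurationError(
            f"{len(stray)} hits outside the universe, e.g. {sorted(stray)[:3]}"
        )
    n_universe = len(annotations.universe)
    rows = []
    for name, members in annotations.sets.items():
        a = len(hit_set & members)
        b = len(hit_set) - a
        c = len(members) - a
        d = n_universe - a - b - c
        odds, p = fisher_test_counts(a, b, c, d)
        rows.append({
            "set_name": name,
            "description": annotations.descriptions.get(name, ""),
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": odds,
            "p": p,
        })
    out = pd.DataFrame(rows).set_index("set_name")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["enriched"] = (out["q"] <= alpha) & (out["odds_ratio"] > 1)
    return out.sort_values("p")
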