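"""Zotu community summaries of heavy versus light gradient fractions.

Relative abundance, clade composition, top-N taxa, and a simple active-taxon
classification contrasting the 15N heavy fractions with a reference group
(typically light fractions of the unamended control): a Zotu is "active" when
it is sufficiently abundant in the heavy fractions, and "enriched" when its
heavy-fraction relative abundance exceeds a fold threshold over the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ZotuTable:
    """Zotu x sample count matrix with sample metadata and taxonomy.

    ``counts``: DataFrame indexed by Zotu id, columns are sample ids,
    non-negative integer counts. ``metadata``: DataFrame indexed by sample id
    (columns such as soil, treatment, fraction_class in {HF, light, bulk}).
    ``taxonomy``: DataFrame indexed by Zotu id with at least a ``clade``
    column; ``gene`` and ``genus`` columns are used where present.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.counts.index.duplicated().any():
            raise ValueError("Zotu ids must be unique")
        missing = self.counts.index.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"Zotus missing from taxonomy: {sorted(missing)[:5]}")
        unknown = set(self.counts.columns) - set(self.metadata.index)
        if unknown:
            raise ValueError(f"samples missing from metadata: {sorted(unknown)[:5]}")

    def samples_where(self, **criteria: str) -> list[str]:
        """Sample ids whose metadata match all given column=value criteria."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, value in criteria.items():
            mask &= self.metadata[col] == value
        chosen = self.metadata.index[mask]
        return [s for s in self.counts.columns if s in set(chosen)]


@dataclass(frozen=True)
class CladeComposition:
    """Per-clade relative abundance (%) of one sample group."""

    percent: pd.Series  # indexed by clade, sums to 100
    reads: pd.Series  # raw read counts per clade
    total_reads: int

    def __post_init__(self) -> None:
        if abs(self.percent.sum() - 100.0) > 0.01:
            raise ValueError("clade percentages must sum to 100 +/- 0.01")


def _pooled_counts(table: ZotuTable, samples: Sequence[str]) -> pd.Series:
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample group")
    missing = set(samples) - set(table.counts.columns)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")
    return table.counts[samples].sum(axis=1)


def relative_abundance(table: ZotuTable, samples: Sequence[str]) -> pd.Series:
    """Per-Zotu proportions within a sample group.

    Counts are pooled (summed) across the group's samples before dividing by
    the group total, matching read-count semantics; proportions sum to 1.
    """
    pooled = _pooled_counts(table, samples)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("sample group has zero total counts")
    return pooled / total


def clade_composition(table: ZotuTable, samples: Sequence[str]) -> CladeComposition:
    """Per-clade percentage composition of a sample group.

    Percentages are 100 * clade reads / group reads; clades present in the
    taxonomy but absent from the group report 0.
    """
    pooled = _pooled_counts(table, samples)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("sample group has zero total counts")
    clades = table.taxonomy.loc[pooled.index, "clade"]
    reads = pooled.groupby(clades).sum()
    all_clades = pd.Index(sorted(table.taxonomy["clade"].unique()))
    reads = reads.reindex(all_clades, fill_value=0)
    percent = 100.0 * reads / total
    return CladeComposition(percent=percent, reads=reads, total_reads=int(total))


def top_n_taxa(
    table: ZotuTable,
    samples: Sequence[str],
    n: int,
    level: str = "zotu",
) -> pd.Series:
    """Most abundant taxa of a group, descending relative abundance.

    ``level`` selects the taxonomy roll-up: ``zotu`` (no roll-up), ``genus``
    or ``clade``. Ties are broken lexicographically by taxon id. Returns at
    most ``n`` entries (all taxa when fewer exist) as a Series of
    proportions indexed by taxon.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rel = relative_abundance(table, samples)
    if level != "zotu":
        if level not in table.taxonomy.columns:
            raise ValueError(f"taxonomy has no {level!r} column")
        rel = rel.groupby(table.taxonomy.loc[rel.index, level]).sum()
    order = sorted(rel.index, key=lambda t: (-rel[t], str(t)))
    return rel.loc[order[:n]]


def active_taxa(
    table: ZotuTable,
    hf_samples: Sequence[str],
    reference_samples: Sequence[str],
    min_abund: float = 0.01,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Classify Zotus as active/enriched in the 15N heavy fractions.

    A Zotu is flagged ``active`` when its heavy-fraction relative abundance
    reaches ``min_abund``; it is additionally ``enriched`` when that
    abundance is at least ``fold`` times its reference relative abundance
    (a Zotu absent from the reference is enriched iff active). Returns a
    DataFrame indexed by Zotu with columns ``hf_rel``, ``ref_rel``,
    ``active``, ``enriched``, sorted by descending heavy-fraction abundance.
    """
    if min_abund < 0 or fold <= 0:
        raise ValueError("min_abund must be >= 0 and fold > 0")
    hf_rel = relative_abundance(table, hf_samples)
    ref_rel = relative_abundance(table, reference_samples)
    df = pd.DataFrame({"hf_rel": hf_rel, "ref_rel": ref_rel}).fillna(0.0)
    df["active"] = (df["hf_rel"] >= min_abund) & (df["hf_rel"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        enriched_vs_ref = df["hf_rel"] >= fold * df["ref_rel"]
    df["enriched"] = df["active"] & np.where(df["ref_rel"] > 0, enriched_vs_ref, True)
    order = sorted(df.index, key=lambda t: (-df.loc[t, "hf_rel"], str(t)))
    return df.loc[order]
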