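"""Nitrification activity metrics and their statistics.

Net nitrification rate (NO3--N accumulation per incubation day), NH4+
accumulation, acetylene inhibition percentage, the log10 transform applied to
gene abundances before comparison, and a classical one-way ANOVA at the 5%
significance level, with optional Welch/Holm pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ChemTimeSeries:
    """NH4+-N and NO3--N concentrations (mg N/kg dry soil) over time."""

    soil: str
    treatment: str
    replicate: str
    days: tuple[float, ...]
    nh4: tuple[float, ...]
    no3: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        if len(d) != len(self.nh4) or len(d) != len(self.no3):
            raise ValueError("days, nh4 and no3 must align")
        if np.any(d < 0) or np.any(np.diff(d) < 0):
            raise ValueError("days must be non-negative and sorted")
        if min(self.nh4, default=0.0) < 0 or min(self.no3, default=0.0) < 0:
            raise ValueError("concentrations must be non-negative")

    def at_day(self, day: float) -> tuple[float, float]:
        """(NH4+, NO3-) at the closest sampled day."""
        d = np.asarray(self.days)
        i = int(np.argmin(np.abs(d - day)))
        return self.nh4[i], self.no3[i]


@dataclass(frozen=True)
class SoilMetadata:
    """Basic physicochemical soil properties (one row per soil)."""

    soil: str
    ph: float
    tc: float  # total carbon, g/kg
    tn: float  # total nitrogen, g/kg
    nh4: float  # mg/kg
    no3: float  # mg/kg
    ap: float = float("nan")  # available phosphorus, mg/kg
    ak: float = float("nan")  # available potassium, mg/kg
    doc: float = float("nan")  # dissolved organic carbon, mg/kg
    clay: float = float("nan")  # %
    silt: float = float("nan")
    sand: float = float("nan")

    def __post_init__(self) -> None:
        if self.tn <= 0:
            raise ValueError("total nitrogen must be positive")
        texture = (self.clay, self.silt, self.sand)
        if all(np.isfinite(texture)) and abs(sum(texture) - 100.0) > 0.5:
            raise ValueError("soil texture percentages must sum to 100 +/- 0.5")


def cn_ratio(meta_or_tc: SoilMetadata | float, tn: float | None = None) -> float:
    """Total carbon over total nitrogen (both g/kg), dimensionless.

    Accepts either a :class:`SoilMetadata` or the two values directly.
    """
    if isinstance(meta_or_tc, SoilMetadata):
        tc, tn = meta_or_tc.tc, meta_or_tc.tn
    else:
        tc = float(meta_or_tc)
        if tn is None:
            raise TypeError("tn required when passing TC directly")
    if tn <= 0:
        raise ValueError("total nitrogen must be positive")
    return tc / tn


def net_nitrification_rate(no3_start: float, no3_end: float, days: float) -> float:
    """Net nitrification rate, mg N kg^-1 dry soil day^-1.

    NO3--N accumulation over the incubation divided by its length; negative
    values (net immobilization) are reported, not clipped.
    """
    if days <= 0:
        raise ValueError("incubation length must be positive")
    return (no3_end - no3_start) / days


def nh4_accumulation(nh4_start: float, nh4_end: float) -> float:
    """Net NH4+-N change over the incubation, mg N/kg dry soil."""
    return nh4_end - nh4_start


def inhibition_percent(delta_inhibited: float, delta_uninhibited: float) -> float:
    """Percent inhibition of NO3- production by an inhibitor treatment.

    100 * (1 - delta_inhibited / delta_uninhibited), clipped to [0, 100].
    ``delta_*`` are NO3--N accumulations over the same incubation with and
    without the inhibitor.
    """
    if delta_uninhibited <= 0:
        raise ValueError("uninhibited NO3- accumulation must be positive")
    return float(np.clip(100.0 * (1.0 - delta_inhibited / delta_uninhibited), 0.0, 100.0))


def log10_abundance(values: Sequence[float]) -> np.ndarray:
    """Elementwise log10 of gene abundances, the transform applied before ANOVA.

    Raises on non-positive values, naming the offending record.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"abundance at position {i} is {arr[i]!r}; log10 needs positive values")
    return np.log10(arr)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float, int, int]:
    """Classical one-way ANOVA across >= 2 groups.

    Returns ``(F, p, df_between, df_within)`` from the standard decomposition
    F = (SSB/df1) / (SSW/df2) with p from the upper tail of the F
    distribution; compare p against the 5% significance level. A fully
    degenerate input (zero between- and within-group variance) yields F = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0, df_between, df_within
        return float("inf"), 0.0, df_between, df_within
    F = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), p, df_between, df_within


def pairwise_welch_holm(
    groups: dict[str, Sequence[float]],
) -> list[tuple[str, str, float, float, float]]:
    """Pairwise Welch t-tests with Holm correction (post-hoc extension).

    Returns (label_a, label_b, t, raw_p, holm_p) per pair. This goes beyond
    the omnibus ANOVA; it is an optional report, not part of the core chain.
    """
    pairs = list(combinations(sorted(groups), 2))
    raw: list[tuple[str, str, float, float]] = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        raw.append((a, b, float(t), float(p)))
    order = np.argsort([r[3] for r in raw])
    m = len(raw)
    holm = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        adj = min(1.0, (m - rank) * raw[i][3])
        running = max(running, adj)  # enforce monotonicity
        holm[i] = running
    return [(a, b, t, p, hp) for (a, b, t, p), hp in zip(raw, holm)]
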