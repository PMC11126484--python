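"""Heavy-fraction quantification of isotopically labeled DNA.

Implements the quantification chain used in DNA-SIP studies of ammonia
oxidizers: conversion of refractive index to CsCl buoyant density, per-profile
normalization of qPCR gene-copy counts across the 16 gradient fractions,
identification of the "heavy" fractions (HF) by comparing the profile from a
15N-substrate microcosm with its 14N counterpart, the HF ratio (share of gene
copies banding in the HF), and the estimated 15N-labeled population abundance

    A_label = R_HF * A_total,

the HF ratio multiplied by the marker-gene abundance measured in total DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Standard CsCl calibration: buoyant density (g/mL, 25 degC) from refractive
# index at the sodium D line.
_RI_SLOPE = 10.8601
_RI_INTERCEPT = -13.4974

# Plausible refractive-index window for CsCl gradients used for DNA banding.
_RI_MIN, _RI_MAX = 1.37, 1.42


class NoSignalError(ValueError):
    """Raised when a profile carries no gene copies in any fraction."""


@dataclass(frozen=True)
class FractionProfile:
    """qPCR gene-copy profile of one gene across one density gradient.

    Parameters
    ----------
    gene:
        Marker-gene / population label (e.g. ``AOA``, ``AOB``, ``ComA``).
    treatment:
        Microcosm treatment the gradient came from (e.g. ``15N-urea``).
    fraction_index:
        1-based fraction indices; fraction 1 is collected from the gradient
        bottom and is the heaviest.
    buoyant_density:
        Buoyant density of each fraction, g/mL; strictly monotone in index.
    copies:
        Gene copies per fraction (per g dry soil); non-negative.
    soil, replicate:
        Free-form sample labels.
    """

    gene: str
    treatment: str
    fraction_index: tuple[int, ...]
    buoyant_density: tuple[float, ...]
    copies: tuple[float, ...]
    soil: str = ""
    replicate: str = "1"

    def __post_init__(self) -> None:
        idx = np.asarray(self.fraction_index, dtype=int)
        bd = np.asarray(self.buoyant_density, dtype=float)
        cp = np.asarray(self.copies, dtype=float)
        if not (len(idx) == len(bd) == len(cp)):
            raise ValueError("fraction_index, buoyant_density and copies must align")
        if len(idx) < 2:
            raise ValueError("a profile needs at least two fractions")
        if len(set(idx.tolist())) != len(idx):
            raise ValueError("fraction indices must be unique")
        order = np.argsort(idx)
        if not np.array_equal(idx[order], np.arange(idx.min(), idx.min() + len(idx))):
            raise ValueError("fraction indices must be contiguous")
        diffs = np.diff(bd[order])
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("buoyant density must be strictly monotone across fractions")
        if np.any(cp < 0):
            raise ValueError("copies must be non-negative")
        # store sorted by fraction index
        object.__setattr__(self, "fraction_index", tuple(int(i) for i in idx[order]))
        object.__setattr__(self, "buoyant_density", tuple(float(x) for x in bd[order]))
        object.__setattr__(self, "copies", tuple(float(x) for x in cp[order]))

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_index)

    def copies_array(self) -> np.ndarray:
        return np.asarray(self.copies, dtype=float)

    def bd_of(self, index: int) -> float:
        """Buoyant density of fraction ``index``."""
        return self.buoyant_density[self.fraction_index.index(index)]

    def same_grid(self, other: "FractionProfile", atol: float = 1e-9) -> bool:
        return self.fraction_index == other.fraction_index and np.allclose(
            self.buoyant_density, other.buoyant_density, atol=atol
        )


@dataclass(frozen=True)
class LabelingEstimate:
    """Result of heavy-fraction quantification for one gene/profile pair."""

    gene: str
    hf_set: frozenset[int]
    hf_ratio: float
    total_abundance: float
    labeled_abundance: float
    peak_bd: float
    soil: str = ""
    replicate: str = "1"

    def __post_init__(self) -> None:
        if not self.hf_set:
            raise ValueError("hf_set must be non-empty")
        if not 0.0 <= self.hf_ratio <= 1.0:
            raise ValueError("hf_ratio must lie in [0, 1]")
        if self.labeled_abundance > self.total_abundance * (1 + 1e-12):
            raise ValueError("labeled abundance cannot exceed total abundance")


def ri_to_bd(refractive_index: float | np.ndarray) -> float | np.ndarray:
    """Convert a CsCl refractive index to buoyant density (g/mL).

    Uses the standard linear calibration rho = 10.8601 * RI - 13.4974,
    valid for the RI window of DNA-banding CsCl gradients. An RI of 1.4015
    (the loading density of the gradients modelled here) maps to 1.7230 g/mL.
    """
    ri = np.asarray(refractive_index, dtype=float)
    if np.any((ri < _RI_MIN) | (ri > _RI_MAX)):
        raise ValueError(
            f"refractive index outside plausible CsCl range [{_RI_MIN}, {_RI_MAX}]"
        )
    bd = _RI_SLOPE * ri + _RI_INTERCEPT
    return float(bd) if np.isscalar(refractive_index) else bd


def normalize_profile(profile: FractionProfile) -> np.ndarray:
    """Scale a profile's copies to its own maximum.

    Returns per-fraction values in [0, 1] (the ratio of each fraction's gene
    copy number to the maximum over the 16 fractions), ordered by fraction
    index. Raises :class:`NoSignalError` for an all-zero profile.
    """
    copies = profile.copies_array()
    peak = copies.max()
    if peak <= 0:
        raise NoSignalError(
            f"profile {profile.gene}/{profile.treatment} has no signal in any fraction"
        )
    return copies / peak


def peak_bd(profile: FractionProfile) -> float:
    """Buoyant density of the maximum-copy fraction.

    Ties are broken toward the heavier fraction: isotope labeling manifests
    as heavy-side mass, so an ambiguous peak is read conservatively heavy.
    """
    copies = profile.copies_array()
    if copies.max() <= 0:
        raise NoSignalError("cannot locate the peak of an all-zero profile")
    bd = np.asarray(profile.buoyant_density)
    at_max = np.flatnonzero(copies == copies.max())
    return float(bd[at_max].max())


def identify_heavy_fractions(
    profile15: FractionProfile,
    profile14: FractionProfile,
    margin: float = 0.10,
    manual_set: Iterable[int] | None = None,
) -> frozenset[int] | None:
    """Identify the heavy fractions (HF) from paired 15N/14N profiles.

    A fraction belongs to the HF when it lies on the heavy side of the
    14N-treatment peak and its normalized 15N signal exceeds the normalized
    14N signal by at least ``margin``. The returned set is the contiguous run
    of such fractions containing the 15N peak fraction. Returns ``None``
    ("no labeling detected") when the 15N peak does not qualify — e.g. when
    the two profiles coincide.

    ``manual_set`` short-circuits detection and returns the given fractions
    verbatim (validated against the grid), supporting HF ranges chosen by
    inspection of the published profiles.
    """
    if manual_set is not None:
        chosen = frozenset(int(i) for i in manual_set)
        bad = chosen - set(profile15.fraction_index)
        if bad:
            raise ValueError(f"manual HF fractions not on the grid: {sorted(bad)}")
        if not chosen:
            raise ValueError("manual HF set must be non-empty")
        return chosen
    if not profile15.same_grid(profile14):
        raise ValueError("15N and 14N profiles must share the fraction grid")
    if margin < 0:
        raise ValueError("margin must be non-negative")

    norm15 = normalize_profile(profile15)
    norm14 = normalize_profile(profile14)
    idx = np.asarray(profile15.fraction_index)
    bd = np.asarray(profile15.buoyant_density)

    bd14_peak = peak_bd(profile14)
    bd15_peak = peak_bd(profile15)
    heavy_side = bd >= bd14_peak - 1e-12
    qualifies = heavy_side & (norm15 - norm14 >= margin - 1e-12)

    # position of the 15N peak fraction (heavier tie-break, as in peak_bd)
    copies15 = profile15.copies_array()
    at_max = np.flatnonzero(copies15 == copies15.max())
    peak_pos = at_max[np.argmax(bd[at_max])]
    if not qualifies[peak_pos]:
        return None
    if abs(bd[peak_pos] - bd15_peak) > 1e-12:  # pragma: no cover - defensive
        raise AssertionError("peak bookkeeping out of sync")

    lo = hi = peak_pos
    while lo > 0 and qualifies[lo - 1]:
        lo -= 1
    while hi < len(idx) - 1 and qualifies[hi + 1]:
        hi += 1
    return frozenset(int(i) for i in idx[lo : hi + 1])


def hf_ratio(profile: FractionProfile, hf_set: Iterable[int]) -> float:
    """Share of a profile's raw gene copies that band in the heavy fractions.

    R = sum of copies over the HF divided by the sum over all fractions.
    Computed on raw copies, not normalized values: the ratio of copy numbers
    is what scales the total-DNA abundance into a labeled abundance.
    """
    hf = set(int(i) for i in hf_set)
    if not hf:
        raise ValueError("hf_set must be non-empty")
    bad = hf - set(profile.fraction_index)
    if bad:
        raise ValueError(f"hf_set contains unknown fractions: {sorted(bad)}")
    copies = profile.copies_array()
    total = copies.sum()
    if total <= 0:
        raise NoSignalError("cannot form an HF ratio from an all-zero profile")
    mask = np.isin(np.asarray(profile.fraction_index), sorted(hf))
    return float(copies[mask].sum() / total)


def labeled_abundance(R: float, A_total: float) -> float:
    """Estimated 15N-labeled population abundance, copies per g dry soil.

    Multiplies the HF ratio by the gene copy number measured in the total
    (unfractionated) DNA.
    """
    if not 0.0 <= R <= 1.0:
        raise ValueError("HF ratio must lie in [0, 1]")
    if A_total < 0:
        raise ValueError("total abundance must be non-negative")
    return R * A_total


def estimate_labeling(
    profile15: FractionProfile,
    profile14: FractionProfile,
    total_abundance: float,
    margin: float = 0.10,
    manual_set: Iterable[int] | None = None,
) -> LabelingEstimate | None:
    """Run the full quantification chain for one replicate of one gene.

    Returns ``None`` when no labeling is detected (and no manual HF set is
    supplied).
    """
    hf = identify_heavy_fractions(profile15, profile14, margin=margin, manual_set=manual_set)
    if hf is None:
        return None
    R = hf_ratio(profile15, hf)
    return LabelingEstimate(
        gene=profile15.gene,
        hf_set=hf,
        hf_ratio=R,
        total_abundance=float(total_abundance),
        labeled_abundance=labeled_abundance(R, total_abundance),
        peak_bd=peak_bd(profile15),
        soil=profile15.soil,
        replicate=profile15.replicate,
    )


def summarize_replicates(estimates: Sequence[LabelingEstimate]) -> pd.DataFrame:
    """Mean +/- standard error of labeling estimates across replicates.

    Estimates are computed per replicate and then averaged, matching how
    replicate microcosms are reported (mean ± SE); the mean of per-replicate
    products R_i * A_i generally differs slightly from the product of the
    means, which is why such summaries rarely factor exactly.
    """
    if not estimates:
        raise ValueError("no estimates to summarize")
    df = pd.DataFrame(
        {
            "soil": [e.soil for e in estimates],
            "gene": [e.gene for e in estimates],
            "hf_ratio": [e.hf_ratio for e in estimates],
            "total_abundance": [e.total_abundance for e in estimates],
            "labeled_abundance": [e.labeled_abundance for e in estimates],
            "peak_bd": [e.peak_bd for e in estimates],
        }
    )

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    out = df.groupby(["soil", "gene"], sort=True).agg(
        n=("hf_ratio", "size"),
        hf_ratio_mean=("hf_ratio", "mean"),
        hf_ratio_se=("hf_ratio", _sem),
        total_abundance_mean=("total_abundance", "mean"),
        labeled_abundance_mean=("labeled_abundance", "mean"),
        labeled_abundance_se=("labeled_abundance", _sem),
        peak_bd_mean=("peak_bd", "mean"),
    )
    return out.reset_index()
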