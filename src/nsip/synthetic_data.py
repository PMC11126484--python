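"""Synthetic CsCl gradient banding and urea-microcosm nitrogen dynamics.

Two generators provide ground-truth test harnesses for the SIP quantification
pipeline:

* :func:`simulate_gradient` bands each simulated nitrifier population as a
  Gaussian over buoyant density (mean set by GC content and 15N atom
  fraction), integrates the band over 16 contiguous fraction windows, and
  applies multiplicative (log-normal) qPCR noise with a detection floor.
* :func:`simulate_microcosm` integrates a two-pool first-order model
  (urea -> NH4+ -> NO3-) of a urea-amended soil microcosm, with optional
  acetylene-style inhibition of ammonia oxidation.

Isotope physics
---------------
Unlabeled DNA bands at rho0(GC) = 1.660 + 0.098*GC g/mL, the standard CsCl
GC-density relation. Full 15N substitution raises the band by a
mass-proportional shift: a base pair carries 7 + GC nitrogen atoms (A·T has
7, G·C has 8), each substitution adds 0.9970 g/mol, and the free-acid pair
mass interpolates between 617.4 (A·T) and 618.4 (G·C) g/mol, giving

    delta_rho = a * rho0(GC) * (7 + GC) * 0.9970 / M_bp(GC)

for atom fraction a — about 0.02 g/mL at full labeling, roughly half the
corresponding 13C shift because nitrogen is the scarcer genome constituent
(genomic C/N is about 2.1:1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from nsip.sip_quant import FractionProfile
from nsip.nitrogen_dynamics import ChemTimeSeries

# GC -> buoyant density calibration (g/mL)
_BD_AT = 1.660
_BD_GC_SLOPE = 0.098

# per-base-pair isotope bookkeeping
_N_ATOMS_AT = 7.0  # nitrogen atoms in an A·T pair; G·C has one more
_DELTA_M_N = 0.9970  # g/mol gained per 14N -> 15N substitution
_MASS_AT = 617.4  # free-acid molar mass of an A·T pair, g/mol
_MASS_GC = 618.4  # ... of a G·C pair


@dataclass(frozen=True)
class TaxonSpec:
    """One simulated nitrifier population in the gradient.

    ``atom15n`` is the 15N atom fraction of its DNA (0 = natural abundance,
    ~0.99 after growth on 99 atom% 15N-urea); ``band_sigma`` is the standard
    deviation of its buoyant-density band (g/mL)."""

    name: str
    total_copies: float
    gc: float
    atom15n: float
    band_sigma: float = 0.004
    gene: str = "AOB"

    def __post_init__(self) -> None:
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        if not 0.0 <= self.atom15n <= 1.0:
            raise ValueError("atom15n must lie in [0, 1]")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")


@dataclass(frozen=True)
class GradientProtocol:
    """Fractionation protocol: how the gradient is cut into fractions.

    Fraction 1 is collected from the gradient bottom (heaviest); indices
    increase toward lighter density. ``qpcr_noise_sigma`` is the standard
    deviation of the multiplicative qPCR noise on the log10 scale;
    ``detection_floor`` zeroes fractions below the assay detection limit."""

    n_fractions: int = 16
    fraction_volume: float = 330.0  # µL
    bd_top: float = 1.660  # g/mL, lightest fraction (index n_fractions)
    bd_bottom: float = 1.780  # g/mL, heaviest fraction (index 1)
    qpcr_noise_sigma: float = 0.1
    detection_floor: float = 10.0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("need at least two fractions")
        if self.bd_bottom <= self.bd_top:
            raise ValueError("bd_bottom must exceed bd_top")
        if self.qpcr_noise_sigma < 0:
            raise ValueError("qpcr_noise_sigma must be >= 0")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")
        if self.fraction_volume <= 0:
            raise ValueError("fraction_volume must be positive")

    def window_edges(self) -> np.ndarray:
        """BD edges of the fraction windows, heaviest first, length n+1."""
        return np.linspace(self.bd_bottom, self.bd_top, self.n_fractions + 1)

    def fraction_centers(self) -> np.ndarray:
        edges = self.window_edges()
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def fraction_width(self) -> float:
        return (self.bd_bottom - self.bd_top) / self.n_fractions


@dataclass(frozen=True)
class MicrocosmParams:
    """Two-pool urea microcosm: urea -> NH4+ (hydrolysis) -> NO3- (nitrification).

    ``urea_doses`` lists (day, mg N/kg dry soil) additions to the urea pool;
    the default is four weekly doses of 100 mg N/kg. ``inhibition_factor``
    scales down ammonia oxidation (1 = complete acetylene block)."""

    nh4_0: float = 0.0
    no3_0: float = 0.0
    urea_doses: tuple[tuple[float, float], ...] = (
        (0.0, 100.0),
        (7.0, 100.0),
        (14.0, 100.0),
        (21.0, 100.0),
    )
    hydrolysis_rate: float = 0.5  # day^-1
    nitrification_rate_constant: float = 0.02  # day^-1
    inhibition_factor: float = 0.0
    duration: float = 28.0  # days
    dt: float = 0.25  # days

    def __post_init__(self) -> None:
        if min(self.nh4_0, self.no3_0) < 0:
            raise ValueError("initial concentrations must be >= 0")
        if self.hydrolysis_rate < 0 or self.nitrification_rate_constant < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.inhibition_factor <= 1.0:
            raise ValueError("inhibition_factor must lie in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if any(day < 0 or amount < 0 for day, amount in self.urea_doses):
            raise ValueError("urea doses must have non-negative day and amount")
        object.__setattr__(
            self,
            "urea_doses",
            tuple((float(d), float(a)) for d, a in self.urea_doses),
        )


@dataclass(frozen=True)
class GradientDataset:
    """Simulated gradient run: true taxa, protocol, and per-gene profiles.

    ``profiles`` maps (gene, treatment) to the observed
    :class:`~nsip.sip_quant.FractionProfile`."""

    taxa: tuple[TaxonSpec, ...]
    protocol: GradientProtocol
    seed: int
    profiles: dict[tuple[str, str], FractionProfile] = field(default_factory=dict)

    def profile(self, gene: str, treatment: str) -> FractionProfile:
        return self.profiles[(gene, treatment)]


def unlabeled_density(gc: float | np.ndarray) -> float | np.ndarray:
    """Buoyant density (g/mL) of unlabeled DNA of the given GC fraction.

    rho0 = 1.660 + 0.098 * GC; strictly increasing in GC. Places typical
    soil nitrifier genomes (GC 0.45-0.60) in the observed 1.70-1.72 g/mL
    band of unlabeled gradient profiles.
    """
    g = np.asarray(gc, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ValueError("gc must lie in [0, 1]")
    rho = _BD_AT + _BD_GC_SLOPE * g
    return float(rho) if np.isscalar(gc) else rho


def label_shift(atom15n: float, gc: float) -> float:
    """Buoyant-density increase (g/mL) from 15N substitution.

    Mass-proportional: delta_rho = a * rho0 * (N_bp * delta_m) / M_bp with
    N_bp = 7 + GC nitrogen atoms per base pair, delta_m = 0.9970 g/mol per
    substituted atom, and M_bp interpolating the free-acid pair masses
    (A·T 617.4, G·C 618.4 g/mol). Linear in the atom fraction; ~0.0207 g/mL
    at full labeling of a 50% GC genome.
    """
    if not 0.0 <= atom15n <= 1.0:
        raise ValueError("atom15n must lie in [0, 1]")
    rho0 = unlabeled_density(gc)  # validates gc
    n_atoms = _N_ATOMS_AT + gc
    m_bp = _MASS_AT + (_MASS_GC - _MASS_AT) * gc
    return atom15n * rho0 * n_atoms * _DELTA_M_N / m_bp


def band_center(taxon: TaxonSpec, treatment: str) -> float:
    """Buoyant density at which a taxon's DNA bands under a treatment."""
    rho = unlabeled_density(taxon.gc)
    if treatment == "15N":
        rho += label_shift(taxon.atom15n, taxon.gc)
    elif treatment != "14N":
        raise ValueError("treatment must be '14N' or '15N'")
    return float(rho)


def _expected_fraction_copies(
    taxa: Sequence[TaxonSpec], protocol: GradientProtocol, treatment: str
) -> dict[str, np.ndarray]:
    """Noise-free expected copies per fraction, summed per gene."""
    edges = protocol.window_edges()  # heaviest first
    # terminal windows capture the full tails: fractionation collects all DNA
    hi = edges[:-1].copy()
    lo = edges[1:].copy()
    hi[0] = np.inf
    lo[-1] = -np.inf
    per_gene: dict[str, np.ndarray] = {}
    for taxon in taxa:
        mu = band_center(taxon, treatment)
        mass = norm.cdf(hi, loc=mu, scale=taxon.band_sigma) - norm.cdf(
            lo, loc=mu, scale=taxon.band_sigma
        )
        expected = taxon.total_copies * mass
        per_gene[taxon.gene] = per_gene.get(taxon.gene, 0.0) + expected
    return per_gene


def simulate_gradient(
    taxa: Sequence[TaxonSpec],
    protocol: GradientProtocol,
    treatment: str,
    seed: int,
) -> GradientDataset:
    """Simulate one fractionated CsCl gradient under one treatment.

    Each taxon bands as a Gaussian centered at rho0(GC) (plus the isotope
    shift under the 15N treatment); expected copies in a fraction are the
    band mass over that fraction's BD window times the taxon's total copies.
    Co-amplified taxa of the same gene are summed before one log-normal
    noise draw per fraction (observed = expected * 10^eps,
    eps ~ N(0, qpcr_noise_sigma)); fractions below the detection floor read
    zero. Identical seeds give identical datasets.
    """
    if not taxa:
        raise ValueError("need at least one taxon")
    if treatment not in ("14N", "15N"):
        raise ValueError("treatment must be '14N' or '15N'")
    rng = np.random.default_rng(seed)
    centers = protocol.fraction_centers()
    indices = np.arange(1, protocol.n_fractions + 1)
    profiles: dict[tuple[str, str], FractionProfile] = {}
    for gene, expected in sorted(_expected_fraction_copies(taxa, protocol, treatment).items()):
        observed = np.asarray(expected, dtype=float)
        if protocol.qpcr_noise_sigma > 0:
            eps = rng.normal(0.0, protocol.qpcr_noise_sigma, size=len(observed))
            observed = observed * 10.0**eps
        observed = np.where(observed < protocol.detection_floor, 0.0, observed)
        profiles[(gene, treatment)] = FractionProfile(
            gene=gene,
            treatment=treatment,
            fraction_index=tuple(int(i) for i in indices),
            buoyant_density=tuple(float(b) for b in centers),
            copies=tuple(float(c) for c in observed),
        )
    return GradientDataset(taxa=tuple(taxa), protocol=protocol, seed=seed, profiles=profiles)


def simulate_paired_gradients(
    taxa: Sequence[TaxonSpec],
    protocol: GradientProtocol,
    seed: int,
) -> GradientDataset:
    """Simulate matched 14N and 15N gradients of the same populations.

    The two treatments share the fraction grid and true taxon parameters but
    draw independent qPCR noise (child seeds spawned from ``seed``).
    """
    ss = np.random.SeedSequence(seed)
    child14, child15 = ss.spawn(2)
    ds14 = simulate_gradient(taxa, protocol, "14N", int(child14.generate_state(1)[0] % 2**31))
    ds15 = simulate_gradient(taxa, protocol, "15N", int(child15.generate_state(1)[0] % 2**31))
    profiles = {**ds14.profiles, **ds15.profiles}
    return GradientDataset(taxa=tuple(taxa), protocol=protocol, seed=seed, profiles=profiles)


def integrate_microcosm(params: MicrocosmParams) -> "np.recarray":
    """Forward-Euler trajectory of the urea / NH4+ / NO3- pools.

    Returns a record array with fields ``day``, ``urea``, ``nh4``, ``no3``
    (mg N per kg dry soil) at every integration step. Doses are added to the
    urea pool at the first step whose time reaches the dose day. The scheme
    conserves total nitrogen exactly between doses (the three derivatives
    sum to zero at every step).
    """
    n_steps = int(round(params.duration / params.dt))
    days = np.empty(n_steps + 1)
    urea = np.empty(n_steps + 1)
    nh4 = np.empty(n_steps + 1)
    no3 = np.empty(n_steps + 1)

    k_hyd = params.hydrolysis_rate
    k_nit = params.nitrification_rate_constant * (1.0 - params.inhibition_factor)

    doses = sorted(params.urea_doses)
    dose_i = 0
    u, a, n = 0.0, params.nh4_0, params.no3_0
    t = 0.0
    for step in range(n_steps + 1):
        while dose_i < len(doses) and doses[dose_i][0] <= t + 1e-9:
            u += doses[dose_i][1]
            dose_i += 1
        days[step], urea[step], nh4[step], no3[step] = t, u, a, n
        if step == n_steps:
            break
        hyd = k_hyd * u * params.dt
        nit = k_nit * a * params.dt
        hyd = min(hyd, u)  # a pool cannot go negative within a step
        nit = min(nit, a + hyd)
        u, a, n = u - hyd, a + hyd - nit, n + nit
        t = (step + 1) * params.dt
    out = np.rec.fromarrays([days, urea, nh4, no3], names="day,urea,nh4,no3")
    return out


def simulate_microcosm(
    params: MicrocosmParams,
    seed: int | None = None,
    sample_days: Sequence[float] | None = None,
    noise_sigma: float = 0.0,
    soil: str = "",
    treatment: str = "",
    replicate: str = "1",
) -> ChemTimeSeries:
    """Simulate NH4+/NO3- chemistry of one urea-amended microcosm.

    Integrates :func:`integrate_microcosm` and optionally subsamples the
    trajectory at ``sample_days`` with additive Gaussian measurement noise
    (standard deviation ``noise_sigma`` mg N/kg, truncated at zero).
    """
    traj = integrate_microcosm(params)
    if sample_days is None:
        days = traj.day
        nh4 = traj.nh4
        no3 = traj.no3
    else:
        days = np.asarray(sample_days, dtype=float)
        pos = np.searchsorted(traj.day, days - 1e-9)
        pos = np.clip(pos, 0, len(traj.day) - 1)
        nh4 = traj.nh4[pos]
        no3 = traj.no3[pos]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        nh4 = np.maximum(0.0, nh4 + rng.normal(0.0, noise_sigma, size=len(nh4)))
        no3 = np.maximum(0.0, no3 + rng.normal(0.0, noise_sigma, size=len(no3)))
    return ChemTimeSeries(
        soil=soil,
        treatment=treatment,
        replicate=replicate,
        days=tuple(float(d) for d in days),
        nh4=tuple(float(x) for x in nh4),
        no3=tuple(float(x) for x in no3),
    )


def calibrate_nitrification_rate(
    params: MicrocosmParams,
    target_net_rate: float,
    bracket: tuple[float, float] = (1e-8, 5.0),
) -> MicrocosmParams:
    """Tune the nitrification rate constant to a target net rate.

    Solves for the first-order constant (day^-1) such that
    (NO3(duration) - NO3(0)) / duration equals ``target_net_rate``
    (mg N kg^-1 day^-1), using Brent's method. Returns a new parameter set.
    """
    from scipy.optimize import brentq

    if target_net_rate < 0:
        raise ValueError("target net rate must be non-negative")

    def net_rate(k: float) -> float:
        p = replace(params, nitrification_rate_constant=k)
        traj = integrate_microcosm(p)
        return (traj.no3[-1] - traj.no3[0]) / params.duration

    lo, hi = bracket
    if net_rate(hi) < target_net_rate:
        raise ValueError("target net rate unreachable within the bracket")
    k_star = brentq(lambda k: net_rate(k) - target_net_rate, lo, hi, xtol=1e-12)
    return replace(params, nitrification_rate_constant=float(k_star))
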