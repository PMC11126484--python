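# Methods

## Gradient banding model

Each simulated population's DNA bands as a Gaussian over buoyant density
(BD). The band center of unlabeled DNA follows the standard CsCl
GC–density relation

    rho0(GC) = 1.660 + 0.098 · GC   [g/mL],

which places typical soil-nitrifier genomes (GC 0.35–0.55) in the
1.69–1.72 g/mL range where unlabeled gradient profiles peak. ¹⁵N
substitution raises the center mass-proportionally:

    delta_rho(a, GC) = a · rho0(GC) · (7 + GC) · 0.9970 / M_bp(GC),

where `a` is the ¹⁵N atom fraction of the DNA, `7 + GC` counts nitrogen
atoms per base pair (an A·T pair has 7, a G·C pair 8), 0.9970 g/mol is the
mass gained per ¹⁴N→¹⁵N substitution, and `M_bp` interpolates the free-acid
base-pair masses (617.4 g/mol for A·T, 618.4 for G·C). At full labeling of
a 50% GC genome this gives 0.0207 g/mL — the canonical ≈0.02 g/mL ¹⁵N
shift, roughly half the corresponding ¹³C shift because genomic C/N is
about 2.1:1. The shift is linear in `a`, so partial labeling scales
proportionally.

The band standard deviation defaults to 0.004 g/mL, about half a fraction
width. It is an effective parameter lumping diffusion broadening,
within-population GC heterogeneity and partial labeling spread; the
simulator does not model rotor physics or diffusion times.

## Fractionation and qPCR observation model

The gradient is cut into 16 contiguous windows on a linear BD grid from
1.780 g/mL (fraction 1, gradient bottom, heaviest) to 1.660 g/mL (fraction
16). Fraction 1's window extends to +inf and fraction 16's to −inf, because
fractionating a real gradient collects all loaded DNA; this makes the
noise-free profile conserve total copies to machine precision. Real
gradients are near-linear over the collected range, so a linear grid is
adequate; measured per-fraction BDs (or refractive indices, converted via
`rho = 10.8601·RI − 13.4974`) can be supplied instead when analyzing real
tables.

Expected copies in a fraction are the taxon's total copies times the
Gaussian band mass over the window; co-amplified taxa sharing a marker gene
are summed first. Observed copies apply one multiplicative log-normal error
per fraction, `observed = expected · 10^eps`, `eps ~ N(0, sigma)` with
`sigma = 0.1` on the log10 scale — qPCR error is multiplicative and a
replicate scatter of ~25% (0.1 log units) is typical of environmental
assays. Fractions below a detection floor (10 copies) read zero. All
stochastic steps take an explicit seed; paired ¹⁴N/¹⁵N simulations draw
independent noise from seeds spawned off one parent seed, so runs are
bit-reproducible.

## Heavy-fraction detection and labeling estimate

Profiles are normalized to their own maximum before comparison. The heavy
fractions are the contiguous run, on the heavy side of the ¹⁴N peak and
containing the ¹⁵N peak, where normalized ¹⁵N exceeds normalized ¹⁴N by at
least a margin (default 0.10; ~1 noise standard deviation at the profile
maximum, large enough that coincident profiles essentially never trigger a
call, small enough to keep the shoulders of a genuinely shifted band).
Published HF ranges are typically chosen by inspection, so a manual
override reproduces any stated fraction set verbatim. "No labeling
detected" is a regular outcome (returned as `None`), not an error.

The HF ratio uses raw copies — footing the estimate on copy numbers, not
normalized values, since the two give different ratios. Peak ties break
toward the heavier fraction (labeling is evidenced by heavy-side mass).
Estimates are computed per replicate and then averaged (mean ± SE), which
is why a mean labeled abundance need not equal the product of mean ratio
and mean total abundance.

Under the default observation model, 100 simulated gradients of a fully
labeled 50%-GC population give an HF ratio ≥ 0.85 in every run and a mean
labeled-abundance error under 2%; an unlabeled population never triggers a
labeling call (the false-call path requires the noisy ¹⁴N and ¹⁵N peak
fractions to disagree, a ~10⁻⁴ event per pair). Passing these checks shows
the estimator is consistent under multiplicative noise on a single shifted
band; it does not exercise multi-population mixtures within one gene,
gradient compression artifacts, or partial community labeling, which real
data can show.

## Microcosm nitrogen model

A two-pool first-order chain, integrated by forward Euler at dt = 0.25 d
over 28 d:

    urea --k_h--> NH4+ --k_n·(1−i)--> NO3-

with hydrolysis rate `k_h` (default 0.5 d⁻¹: urea hydrolyzes within days in
soil), nitrification constant `k_n`, and inhibition factor `i` in [0, 1]
(1 = complete acetylene block of ammonia monooxygenase). Four urea doses of
100 mg N/kg enter the urea pool on days 0, 7, 14, 21 (weekly, matching the
four additions over a 28-day incubation). The three derivatives sum to
zero, so total N is conserved exactly between doses — a structural check on
the integrator. Transfers are capped at the donor pool per step so no pool
goes negative at coarse dt. Optional additive Gaussian measurement noise
(default 1.5 mg N/kg in the drivers) applies only at sampled days.

No kinetic model is published for such incubations, so the simplest chain
reproducing the qualitative behavior — NH₄⁺ accumulation under urea,
NO₃⁻ production blocked by acetylene — was chosen, and `k_n` is calibrated
(Brent root find) so the 28-day net nitrification rate hits the anchor
values 2.10 (acidic) and 5.24 (neutral) mg N kg⁻¹ d⁻¹. The model omits
immobilization, ammonia volatilization, nitrite intermediates and
Monod/saturation kinetics; it is a mass-balance harness for the rate
arithmetic, not a biogeochemical model.

Net nitrification rate is NO₃⁻-N accumulation divided by incubation days —
the standard net-rate definition; negative rates (net immobilization) are
reported unclipped. The inhibition percentage,
`100·(1 − ΔNO₃(inhibited)/ΔNO₃(uninhibited))`, is clipped to [0, 100].

## Statistics

Gene abundances are log10-transformed before comparison (they are
log-normally distributed across replicates). The one-way ANOVA uses the
classical decomposition F = (SSB/df₁)/(SSW/df₂) with the upper-tail F
p-value, reported against the 5% significance level. The fully degenerate
case (all values identical) is defined as F = 0, p = 1 rather than NaN.
Pairwise Welch t-tests with Holm correction are available as an optional
post-hoc report — an extension beyond the omnibus test, flagged as such.

## Community summaries

Zotu counts are pooled (summed, not averaged) across replicate samples of a
group before computing proportions, matching read-count semantics. Clade
composition reports percentages over the group total (zero-count clades
included); top-N ranking breaks ties lexicographically by taxon id so
orderings are deterministic; the roll-up level (Zotu, genus, clade) is a
parameter. A Zotu is called **active** when its relative abundance in the
¹⁵N heavy fractions reaches `min_abund` (default 1%), and **enriched** when
it additionally exceeds `fold` (default 2) times its reference relative
abundance; a Zotu absent from the reference is enriched iff active. Both
thresholds are exposed because no formal rule is standard — the defaults
encode "visibly present in the labeled DNA and clearly shifted versus the
control". The reference group (control light fractions vs bulk DNA, and its
sampling day) is user-specified for the same reason. The driver's Zotu
table is synthetic (multinomial reads over clade-weighted Zotus) and says
so; it exercises the bookkeeping, not amplicon biology.

## Analysis drivers and problem sizes

The drivers simulate 2 soils × 2 genes × 3 replicates × 2 treatments of
16-fraction gradients, 18 chemistry series sampled at 5 days, and a
4-sample × 18-Zotu community table — sizes matched to the tabular summaries
the analysis consumes, which keeps the full sequence under a second while
leaving every statistical pathway exercised. The recovery checks use 100
seeds (1..100) to bound the stochastic acceptance rates.

## Known limitations

* The GC→BD and RI→BD calibrations are fixed linear maps; lab-specific
  gradient calibration offsets are not modeled.
* HF detection assumes one dominant band per gene profile; bimodal
  profiles (mixed labeled/unlabeled subpopulations) return the run around
  the taller peak only.
* The microcosm model's two pools cannot represent NH₄⁺ sorption or pH
  feedbacks; calibrated rate constants are effective, not mechanistic.
* Amplicon compositionality (per-sample read-depth artifacts) is not
  corrected; proportions are plain count shares.
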