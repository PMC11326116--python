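# Methods

`idcsim` models interdomain conjugation (IDC) — T4SS-mediated plasmid
transfer from *E. coli* donors to *S. cerevisiae* recipients — in daily
serial-dilution batch cocultures whose population ratios are tuned by
engineered crossfeeding, and implements the measurement statistics used to
quantify such experiments.

## The coculture model

### State and forces

The model tracks six cell pools per 200 µL well — free and clumped donors
(B_f, B_c), recipients (Y_f, Y_c) and transconjugants (T_f, T_c) — four
amino acids (Leu, Trp, Ura, His; well-average µM), glucose (g/L), and a
cumulative conjugation-event counter.  Five processes act:

1. **Growth.** Each population X grows at
   `µ_X · Π_a n_a/(K_a + n_a) · n_G/(K_G + n_G)`, the product running over
   X's required amino acids (its auxotrophies); prototrophs contribute a
   factor of exactly 1.  Growth is glucose-gated for everyone.
2. **Death.** First-order at rate `d_X`.
3. **Secretion and consumption.** Overproducers secrete their amino acid at
   a constant per-cell rate (σ_L per crossfeeder yeast, σ_W per crossfeeder
   bacterium; WT yeast secrete a small basal σ_L,basal that underlies the
   observed commensalism).  Consumption is growth-coupled: each new cell of
   X debits `u_{X,a}` of every nutrient it requires.
4. **Clumping.** Bacteria adhere to yeast-wall mannoproteins, modeled as
   reversible 1:1 pairing with mass-action association `k_a·B_f·(Y_f+T_f)`
   (the partner drawn from Y vs T by relative abundance) and first-order
   dissociation `k_d`.  Free mannose saturates the bacterial receptors:
   the media mannose flag forces `k_a = 0`, and a mid-experiment mannose
   switch additionally releases every clumped cell instantly.
5. **Conjugation.** Recipients convert to transconjugants at
   `γ·D·R/(D+R+T)` within the free compartment and `γ_c·D·R/(D+R+T)` within
   the clumped compartment (per-total-cell collision normalization; a
   Levin-style mass-action-on-densities mode is available by configuration).
   Transconjugants never re-donate, so the conjugative flux cancels exactly
   between the Y and T pools.  With 1,000 donors, 1,000 recipients and the
   literature transfer term γ = 0.004, one unit step yields exactly 2 new
   transconjugants — the per-total-cell form is the default because it
   reproduces this arithmetic.

**Proximity benefit.** Clumped bacteria perceive, on top of the bulk, a
local leucine pool `P · σ · (clumped partners) · τ_loc` — the standing
secretion of their clumped partners scaled by the proximity multiplier P
(τ_loc, default 1 h, is the effective residence time of secreted material
in the clump microenvironment).  This term is phenomenological and
deliberately *not* mass-conserving: it models increased local access
(whether by proximity to secretion, nanotubes, or lysate) without debiting
a bulk pool that never saw the material.  Consequently clumped auxotrophic
bacteria can grow on partner secretion even when bulk leucine reads zero;
the package treats this as the mechanism of the observed commensalism of
leucine-auxotrophic bacteria with WT yeast.

**Plasmid payloads.** Transconjugants inherit recipient kinetics with
marker changes only: a `rescue_markers` payload (URA3/HIS3 on the
transferred plasmid) removes Ura/His from the transconjugant's required
set; a `crispr_cutter` payload destroys the recipient's episomal URA3 so
transconjugants *gain* a uracil requirement (at 0% uracil their counts are
transient snapshots); `crispr_no_oriT` is the transfer-dead control and
contributes exactly zero conjugative flux.

### The batch protocol

Days of 24 h (configurable) are integrated and then diluted 1:10
(0.9 fresh media + 0.1 carryover, the 180 µL + 20 µL transfer), for
`n_days` days.  The dense trace is reported on a 15-minute grid; a
`DailySample` records, at each pre-dilution instant, species totals and the
expected selective-plate CFU = T_total × (100 µL plated / 200 µL well).
The cumulative conjugation counter is an event tally and is not diluted.

### Numerics

The reference integrator is adaptive LSODA (stiff-capable) at rtol 1e-8,
atol 1e-6 cells, with components clipped at zero and clip events logged.
Fitting loops and sweeps use a fixed-step RK4 day integrator compiled with
numba (step = 1/12 of the 15-min sampling interval), cross-checked against
LSODA on day-level totals at 1e-3 relative in the test suite.  Over many
days the two paths can diverge at nutrient-exhaustion boundaries (the
dynamics there are genuinely sensitive); all fitting compares model to data
generated by the same screening path, so this does not bias estimates.

### Default constants and where they come from

The kinetic constants are not published as a table; the defaults are fixed
once from biophysical reasoning and held:

| constant | default | rationale |
|---|---|---|
| µ_B, µ_Y | 0.40, 0.30 /h | minimal-media doubling ~1.7 h (E. coli), ~2.3 h (yeast) |
| d | 0.01 /h | slow basal death/maintenance |
| K_aa | 5 µM | amino-acid half-saturation, low-µM range |
| K_G | 0.2 g/L | glucose half-saturation |
| u_B,aa | 1e-5 µM/cell | leucine requisition incl. overflow; caps bacteria at ~1.1e7/well at 15% LW |
| u_Y,aa | 3.5e-6 µM/cell | tryptophan requisition; caps yeast at ~1.1e7/well at 15% LW |
| u_B,G | 2e-8 g/L/cell | saturation ~5e9/mL in 2% glucose (oxygen/overflow folded in) |
| u_Y,G | 6e-7 g/L/cell | yeast saturation ~1.7e8/mL |
| σ_L (crossfeeder) | 2e-7 µM/h/cell | sustains ~5e6 partner bacteria/day at 1e7 yeast |
| σ_L,basal (WT) | 5e-9 µM/h/cell | low enough that free bacteria wash out at 0% Leu, clumped ones survive at high P |
| σ_W | 5e-8 µM/h/cell | weaker reverse feeding (auxotrophic yeast benefit little) |
| k_a, k_d | 1e-7 /(cell·h), 0.05 /h | ~80% of cells paired at 1e7 cells/well, matching pervasive aggregation seen by microscopy |
| γ, γ_c | 2e-5, 3e-4 | centers of the fitted bands (free / clumped) |
| P, τ_loc | 1, 1 h | proximity benefit off by default; sweeps explore it |

With these defaults the donor-survival crossover in the proximity sweep at
0% leucine falls between P = 100 and P = 1000 (it scales inversely with
σ_basal·Y_c·τ_loc); the package asserts threshold existence, not its
location, which is configuration-dependent.

## Inference

Calibration is staged, mirroring how such models are fit in practice:

1. **Growth constants** (µ_B, µ_Y, u_B,aa, u_Y,aa) are fit to the mannose
   (clump-free) arm with transfer off, using the reduced two-species
   dynamics.  The objective sums (a) squared differences of after-day-1-
   normalized traces on the data grid and (b) 10 × the squared log10
   differences of absolute daily counts.  Both terms are needed: normalized
   shapes alone are nearly scale-invariant in the consumption constants
   (the dual fluorimeter + flow-cytometry measurement scheme is what makes
   them identifiable).
2. **γ** is fit alone against mannose-arm daily transconjugant counts
   (log10 SSE).
3. **γ_c** is fit alone against mannose-free counts with γ held fixed.

Each stage runs iterative Latin Hypercube Sampling: sample `n` vectors
(each marginal stratified, log10-space for rate constants), score, keep the
best fraction (default 0.2), shrink every range to the keepers' min–max
(never expanding, always retaining the incumbent best), resample.  Failed
solves score +inf so the Latin structure of a round is preserved.
Parameter sensitivity is reported as the Spearman rank-correlation
magnitude between sampled values and error, ties broken alphabetically.
A qualitative-check report accompanies each fit: response to amino-acid
supplementation, steady-state survival, and approximate donor-to-recipient
ratio agreement.

Transfer-term search ranges span 1e-7–1e-2, covering the literature value
4e-3 and the fitted bands.  On the packaged pseudo-experiment (ground truth
γ = 2e-5, γ_c = 3e-4, 5% fluorescence CV, Poisson counts), 3 rounds × 500
samples per stage recover γ within a factor of 2 and γ_c inside
[2e-4, 4e-4]; the test suite asserts both in at least 8 of 10 seeded runs.

Sweeps (`parameter_sweep`, `rescue_phase_map`) run the full batch protocol
per grid cell on the screening integrator, annotate cells matching a
supplied experimental value, and never abort on per-cell solver failures.
Rescue classification uses configurable thresholds on the day-final
recipient+transconjugant total (collapse < 1e5, rescued ≥ 5e6 cells/well).

## Quantification statistics

* **Trace normalization** divides every reading by the maximum of its
  measurement type (channel) over all wells of the experiment after day 1
  (24 h); readings before the cutoff may exceed 1.  Per-well normalization
  is available by flag.
* **D:R** divides per-species max-normalized donor counts by normalized
  recipient counts; zero recipients flag a missing value, never infinity.
* **log-log GLM**: normal-family, identity-link fit of log10(IDC) on
  log10(D:R), excluding points at the CFU detection limits (0.1 floor, 500
  lawn cap); equals closed-form least squares to 1e-10.  `daily_slopes`
  repeats the fit per day.
* **ICQ** = (fraction of masked pixels whose mean-centered channel product
  is positive) − ½, in [−0.5, 0.5]; zero products count as non-positive,
  which keeps the identical/complementary channel pair exactly at ±0.5.
  Invariant under positive-gain affine rescaling and channel swap.
* **Fold decrease** = −(normalized monoculture)/(normalized coculture),
  sign convention preserved verbatim (values are negative); zero coculture
  flags a missing value.
* **CFU conventions**: lawns stored at 500; counts ≥ 200 flagged as
  estimates; zero counts stored as 0 with the 0.1 floor substituted only in
  log-scale display values.

## Synthetic data

The generator emulates the measurement chain, not the instruments:
fluorescence = per-cell yield × species total × lognormal(CV 5% default)
on the 15-minute grid (mCherry = bacteria, ymCitrine = all yeast,
yeBFP = transconjugants), monoculture companions by re-running the model
with one species zeroed; flow-like daily counts (Poisson below 1e7, where
sampling noise matters); CFU platings of half the well volume with Poisson
sampling and the counting conventions above; and colony image pairs
(Gaussian-blob or angular-sector textures) whose second channel blends the
first channel (ρ ≥ 0) or its complement (ρ < 0) with an independent
texture, so expected ICQ is monotone in ρ with exact anchors at ρ = ±1.

`make_fixture_suite` packages the full pseudo-experiment: 4 strain pairings
× 4 %LW levels × 6 days, mannose-free and mannose arms, plus images at 7 ρ
levels, with a manifest carrying every ground truth.  What passing tests on
this bundle show is that the pipeline is self-consistent and that the
estimation machinery recovers known parameters under the stated noise; they
do not validate the noise model against real instruments, the absolute
population scales against real flow counts, or the clump-pair geometry
against real aggregate-size distributions.

## Problem sizes used by the packaged checks

The test suite and the acceptance script run entirely at desk scale: 6-day
(occasionally 10–12-day) protocols with 96 samples/day, 256×256 images,
and 3×500-sample fits repeated over 10 seeds — sizes chosen so the whole
suite completes in minutes while leaving every qualitative contrast
(mannose suppression ≥ 10×, rescue differential, transient CRISPR counts)
clearly resolved.

## Known limitations

* Clump pairs are strictly 1:1; real aggregates contain many bacteria per
  yeast and their size distribution matters for both transfer and the
  proximity benefit.
* The proximity pool breaks mass conservation by construction (see above);
  leucine bookkeeping is exact only while bulk concentrations are positive.
* Deterministic continuous dynamics cannot express stochastic
  establishment: any conjugative flux, however small, deterministically
  seeds a growing transconjugant population, so rescue outcomes that are
  bimodal in reality appear graded here.
* The two integration paths diverge quantitatively (not qualitatively) on
  multi-day horizons near nutrient exhaustion; comparisons should stay
  within one path.
* No spatial structure: colonies are emulated statistically for ICQ only.
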