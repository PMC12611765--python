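# Methods

## Mass and composition model

All mass arithmetic is integer element counting over {C, H, D, N, O, P, S,
Na} with monoisotopic atomic masses pinned to the IUPAC 2021 / AME2020
values (H 1.00782503224, D 2.01410177812, C 12 exactly, N 14.00307400446,
O 15.99491461960, P 30.97376199786, S 31.97207117443, Na 22.98976928196 Da;
electron 0.000548579909 Da), so every derived number is bit-stable across
platforms.

Lipid compositions are built from a fixed class table: a fully hydrated
core (backbone + headgroup, e.g. glycerol C3H8O3 for TG/DG,
glycerophosphocholine C8H20NO6P for PC/LPC, cholesterol C27H46O for CE,
sphingosylphosphorylcholine C23H49N2O5P for SM) plus free fatty chains
(acid CnH2n−2dO2, fatty alcohol for O- ethers, one implicit extra double
bond for P- vinyl ethers), condensing one water per ester/amide/ether
linkage. Species-level sum compositions ("TG 56:6") use the same
arithmetic on totals; SM/Cer totals include a d18:1 long-chain base, the
convention used when only a sum composition is reported. Free fatty acids
(`FA18:2`) are the un-esterified chain itself.

Oxidation modifications change composition by: `<OH>` +O, `<OOH>` +2O,
`<oxo>` +O −2H, `<epoxy>` +O. Double-bond counts in the shorthand are
left unchanged by modification, matching common epilipidomics usage.

### Adduct conventions

Two electron-mass conventions coexist in instrument software, and both are
supported per call:

* **proton** (default, physically correct): the ion mass accounts for the
  electrons carried by the charge, so [M+H]+ adds 1.0072765 Da;
* **hydrogen**: neutral-atom masses only, so [M+H]+ adds 1.0078250 Da.

The packaged quinone transition table records which convention each
reference value was printed under (the deuterated CoQ10 product ion
203.11904 is a hydrogen-convention value; all others are proton-convention).
The table's *m/z* columns are recomputed from the formulas at load time and
never stored.

One discrepancy is deliberately not reproduced: the printed CoQ8 MRM rows
pair precursor 744.6 with [M+H]+ and 727.6 with [M+NH4]+, which is inverted
relative to C49H74O4 (computed: [M+H]+ 727.6, [M+NH4]+ 744.6 — the same two
numbers, swapped). The package computes from formulas.

### Kendrick mass defect

KM = m/z × 14 / m(CH2); the defect is nearest-integer(KM) − KM, lying in
[−0.5, 0.5). CH2 homologues share a defect to machine precision, which is
what makes the KMD–RT false-positive filter work.

## In-silico oxidation

"Maximum modification sites" is interpreted as the cap on the number of
modification *groups* per lipid (site-level semantics are not otherwise
defined for sum compositions); this and every other cap is configurable.
Enumeration is exhaustive over count tuples and checked in the test suite
against an independent brute-force oracle across random constraint
settings. Eligibility for oxidation requires ≥1 double bond among the
chains; no per-double-bond capacity is modelled. With chain-resolved
parents the modification set is placed on the most unsaturated chain —
PUFA chains are by far the dominant peroxidation substrates — which is
what makes fragment prediction well-defined; for sum compositions the set
stays at species level and fragment prediction is unavailable.

Top-N target selection sorts by (mean raw intensity desc, name asc) so
ties are reproducible; the optional phenotype-correlated additions use
Pearson correlation and keep only positive correlates. The union is
deduplicated by species identity.

## Inclusion and exclusion lists

Inclusion entries are one per (species, adduct), deduplicated at 5 ppm —
exact isomers (e.g. `<OOH>` vs `<2OH>`, both +2O) therefore collapse to a
single precursor — and sorted by m/z. Iterative exclusion from a prior DDA
run keeps precursors eluting before `max_rt` whose intensity exceeds the
noise floor, defined as the intensity of the `noise_count`-th weakest
retained precursor (the wrapped R package's exact floor formula is not
public; only the four published parameters are treated as normative), and
merges survivors within `mz_window` and `rt_window` into
intensity-weighted centroids.

## Identification

Candidates pass a 5-ppm precursor gate and a precursor-intensity floor;
peaks below 1% of the base peak are ignored. Three scores on a 0–100
scale, with thresholds 60/80/40, decide acceptance. The upstream tool's
score formulas are not public, so the package defines them transparently:

* **score** — fraction of considered ion current explained by predicted
  fragments (×100);
* **isotope score** — cosine similarity between the observed precursor
  isotope envelope (first three isotopologues, when the acquisition
  provides them) and a Poisson-style theoretical envelope from the
  formula; spectra without envelope information pass this gate;
* **rank score** — mean intensity-percentile rank of matched peaks (×100),
  penalising candidates matched only by weak peaks.

**Oxidized-fragment evidence rule.** The manual curation step of the
original workflow is codified: an identification is accepted only if ≥1
matched fragment retains at least one added oxygen. Retention is decided
by formula accounting — water losses are attributed to modification
oxygens (the carboxyl group survives fragmentation), so a fragment retains
added oxygen iff its oxygen count exceeds that of the same fragment built
from the unmodified acyl. This reproduces the field's classification:
`[FA18:2<OOH>-H2O+H]+` retains (2 added − 1 lost = 1), `[FA18:2<OH>-H2O+H]+`
does not (1 − 1 = 0).

**KMD–RT filter.** Within each homologous series (class, ether subclass,
modification set, double-bond count) of ≥3 members, a least-absolute-
deviations line of KMD on RT is fitted (2-parameter IRLS); members whose
MAD-studentized residual exceeds 3.0 are flagged as false positives.
Smaller groups pass unflagged. The MAD scale has a tiny floor (1e−9) so
that exactly collinear series with one gross outlier flag only the
outlier.

**Isomer collapse** groups identifications within 5 ppm at the precursor
level and keeps the highest-scoring representative, mirroring the final
unique-m/z target list of the workflow.

## Quantification

XICs sum centroided intensities within a symmetric ppm tolerance per scan.
Peak areas are trapezoidal above a linear baseline between the integration
window endpoints — a deterministic replacement for manual curation; the
original study's manual Skyline baselines are unknowable, so absolute
agreement with them is not claimed. PRM transitions use only MS2 scans
whose isolation window (default 1.2 Th, configurable) contains the
precursor; transitions without matching scans are flagged per transition,
not fatal. Isotope dilution is the exact ratio
(analyte area / labelled-standard area) × spiked amount. Internal-standard
and protein normalizations are exact ratios and therefore invariant to
global intensity rescaling. External calibration is an ordinary
least-squares line with R² and an extrapolation flag on back-calculation.

## Statistics

Raw → log10 → autoscale, state-checked so stages cannot be skipped or
repeated. Zeros/missing raw values are replaced by one fifth of the
feature's minimum positive value before log10 (a common metabolomics
convention; the replacement is flagged per cell). Autoscaling uses the
n−1 standard deviation; constant features map to zero vectors. The
differential test is Welch's two-sided t-test (the unequal-variance choice
is deliberate; only "two-sided t-test" is specified upstream) on the
processed matrix — autoscaled by default, matching the one-factor
pipeline — with Benjamini–Hochberg q-values; fold changes are always
ratios of raw group means. Volcano labels use strict inequalities
(|FC| > 2, q < 0.05). Clustering is Ward linkage on Euclidean distances
of the processed matrix. Essentiality–metabolite correlation is Pearson
with pairwise-complete NaN handling; metabolites with <3 complete pairs
or zero variance are flagged undefined.

## Kinetics

Inhibited-autoxidation traces are two-phase: slow growth during the lag
while the antioxidant is consumed, then fast propagation. The lag
estimator segments the trace at the breakpoint minimising the two-line
least-squares error and intersects the baseline tangent with the
maximum-slope (propagation) tangent; this is robust to plate-reader gain
(invariant under affine signal scaling) and degrades gracefully with
noise. Traces whose two slopes are indistinguishable (within 10%) from
the start report lag 0 (uninhibited); traces whose total rise stays
within 5× the baseline noise are censored (propagation never began).
Propagation rate is the maximum sliding-window slope, with the window
defaulting to a quarter of the trace because short windows inflate the
maximum of noisy slope estimates. Fewer than 10 points is an error.

## Synthetic data

The generators emulate the *structure* of each input with known ground
truth; identical configurations reproduce identical outputs byte for byte.

* **Lipidome tables** — log-normal intensities with class-specific
  location (TGs brightest, lysolipids dimmest), 20% within-feature
  biological CV, and multiplicative fold changes planted in one group.
  Parameters are a priori choices of realistic magnitudes; nothing is
  fitted to any measured dataset.
* **MS/MS spectra** — a configurable fraction (default 90%) of one
  candidate's predicted fragments with 3-ppm m/z jitter, low-level noise
  peaks, and a realistic precursor isotope envelope; decoys reuse a real
  precursor but randomise fragment m/z, so precursor-level gates stay
  informative. A "nonretaining" mode emits spectra whose only evidence is
  oxygen-losing fragments, to exercise the evidence filter.
* **PRM runs** — Gaussian elution (σ 0.1 min, 0.02-min sampling) with
  area proportional to the planted amount; the SNR option applies
  signal-proportional Gaussian noise of relative s.d. 1/SNR per scan
  (centroided peak intensities scale their noise with signal; additive
  noise on empty tails is not a realistic failure mode for these assays).
* **Kinetic traces** — piecewise-linear lag/propagation with additive
  Gaussian noise; the coupled NADH channel decreases linearly and reaches
  zero exactly at the lag end.
* **KMD–RT series** — a CH2-homologous oxidized-TG series exactly
  collinear in KMD–RT plus one outlier displaced by 10× a nominal σ.

What the generators do **not** emulate — chromatographic drift between
runs, chimeric spectra, isotope envelopes beyond three isotopologues,
electrospray saturation, class-dependent fragmentation efficiency —
bounds what passing tests show about real data: they validate the
computational pipeline, not instrument behaviour.

## Problem sizes and numerical choices

The test suite runs the identification benchmark at 200 true + 200 decoy
spectra against an 84-candidate panel; quantification recovery over 50
seeds; the statistics null calibration at 1,000 features × 200 replicates
(4 vs 4) with the empirical false-discovery proportion compared against
0.05 + 3 Monte-Carlo standard errors; KMD–RT and kinetics recovery over
100 seeds each. These sizes were chosen to make the Monte-Carlo standard
errors small relative to the tested tolerances. ppm tolerances are
symmetric around theoretical m/z. Integration areas are clamped at ≥0.
The LAD fit runs ≤50 IRLS iterations with a 1e−12 weight floor.

## Known limitations

* No sn-position or double-bond-position resolution; sum-composition
  semantics throughout.
* Truncated/core-aldehyde oxidation products are outside the constraint
  vocabulary (as in the prediction settings the defaults mirror).
* Negative-mode TG chemistry and chimeric-spectrum deconvolution are not
  modelled.
* The internal mzML reader covers centroided spectra with 32/64-bit
  float arrays, zlib or no compression — the subset emitted by standard
  converters; vendor raw files are out of scope.
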