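# epilipid

Semi-targeted epilipidomics of oxidized neutral and polar lipids: predict a
sample-specific oxidized lipidome in silico, acquire it by inclusion-list
DDA, identify oxidized species from MS/MS with strict fragment-evidence
rules, and quantify them by parallel reaction monitoring (PRM) and isotope
dilution — together with the one-factor lipidomics statistics and the
inhibited-autoxidation kinetics analysis that accompany such studies.

The package is aimed at lipidomics/redox-biology groups who measure
peroxidation of storage lipids (triacylglycerols, cholesteryl esters in
lipid droplets) and of membrane phospholipids, and who need a reproducible,
scriptable replacement for the manual steps of that workflow.

## What it computes

**In-silico oxidized lipidome.** From a measured lipidome the per-class
top-N most abundant species (and optionally the top-N most positively
phenotype-correlated ones) are selected and expanded combinatorially into
oxidation products carrying hydroxyl (`<OH>`, +O), keto (`<oxo>`, +O −2H),
hydroperoxyl (`<OOH>`, +2O) and epoxide (`<epoxy>`, +O) groups, under caps
on modification sites and total added oxygens (defaults: ≤2 sites, ≤3 O,
≤2 OH, ≤1 oxo, ≤1 OOH, 0 epoxy — 7 modification sets). Precursor *m/z* for
the inclusion list is computed from elemental formulas with monoisotopic
masses; sodiated adducts are used because sodiated oxidized lipids fragment
most informatively.

**Rule-based identification.** A candidate is accepted only when, besides
passing score thresholds, at least one matched fragment is an *oxidized
fatty-acid specific fragment*: the intact oxidized acyl as an adduct ion
(e.g. `[FA18:2<OOH>+Na]+`) or a fragment retaining ≥1 added oxygen after
water loss (e.g. `[FA18:2<OOH>-H2O+H]+`). Fragments that shed every added
oxygen (e.g. `[FA18:2<OH>-H2O+H]+`) carry no modification-specific
information and cannot support a call. Annotations that break the linear
Kendrick-mass-defect vs retention-time trend of their homologous series are
flagged as false positives, and exact isomers are collapsed to unique
*m/z* targets.

**Quantification.** XICs at 5 ppm, trapezoidal integration over a linear
endpoint baseline, PRM transition areas restricted to scans whose isolation
window contains the precursor, per-class internal-standard and per-sample
protein normalization, isotope-dilution absolute amounts
(area ratio × spiked amount), external calibration, and CoQ redox metrics
(total pool, reduced fraction, CoQ per neutral lipid).

**Statistics & kinetics.** log10 → autoscaling, Welch t-tests with
Benjamini–Hochberg FDR, volcano classification at |FC| > 2 and q < 0.05,
Ward clustering, essentiality–metabolite Pearson correlations; lag time and
propagation rate of two-phase inhibited-autoxidation fluorescence traces.

## Worked example

```python
from epilipid import parse_lipid_name, species_formula, adduct_mz
from epilipid.epilipidome import enumerate_oxidized_species
from epilipid.identification import predict_fragments

parent = parse_lipid_name("TG 18:1/18:1/18:2")
products = enumerate_oxidized_species(parent)
print(f"{parent} -> {len(products)} predicted oxidation products")
for ox in products[:3]:
    mz = adduct_mz(species_formula(ox), "[M+Na]+")
    print(f"  {ox.name():28s} {species_formula(ox)}   [M+Na]+ m/z {mz:.4f}")
```

prints

```
TG 18:1/18:1/18:2 -> 7 predicted oxidation products
  TG 18:1/18:1/18:2<oxo>       C57H100O7   [M+Na]+ m/z 919.7361
  TG 18:1/18:1/18:2<OH>        C57H102O7   [M+Na]+ m/z 921.7518
  TG 18:1/18:1/18:2<OOH>       C57H102O8   [M+Na]+ m/z 937.7467
```

— seven oxidation products of the linoleoyl chain under the default caps,
with the sodiated precursor *m/z* that goes onto the inclusion list. The
diagnostic fragments of the hydroperoxide show the evidence rule at work:

```
[FA18:2<OOH>+Na]+          m/z  335.2193  retains added O: True
[FA18:2<OOH>-H2O+Na]+      m/z  317.2087  retains added O: True
[M-FA18:1+Na]+             m/z  655.4908  retains added O: False
```

The intact oxidized acyl and its water loss keep at least one of the two
added oxygens and count as oxidized-lipid-specific evidence; the neutral
loss of an unmodified acyl does not.

A full synthetic end-to-end run (simulated lipidome → target selection →
in-silico oxidation → inclusion list → identification → PRM → statistics):

```
epilipid run-all --seed 1 --out epilipid_out
```

## Layout

- `epilipid.chem` — shorthand parsing, elemental formulas, adduct *m/z*,
  Kendrick mass defect
- `epilipid.epilipidome` — target selection, oxidation combinatorics
- `epilipid.acquisition` — inclusion / iterative-exclusion lists
- `epilipid.identification` — fragment prediction, spectrum matching,
  evidence and KMD–RT filters, isomer collapse
- `epilipid.quantification` — XIC/PRM integration, normalizations,
  isotope dilution, calibration, redox metrics
- `epilipid.statistics` — transforms, Welch/BH testing, clustering,
  correlation
- `epilipid.kinetics` — lag time, propagation rate
- `epilipid.synthetic` — seeded generators for every input, with ground
  truth
- `epilipid.io`, `epilipid.cli`, `epilipid.pipeline` — formats, CLI,
  orchestration

See `docs/methods.md` for the models, conventions and design choices.
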