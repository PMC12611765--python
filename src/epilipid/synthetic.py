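"""Seeded generators for every input the pipeline consumes.

Each generator emulates the *structure* of the corresponding measured
data — log-normally distributed lipid intensities with multiplicative
group effects, centroided MS/MS spectra built from predicted oxidized-
lipid fragments plus decoys and noise, Gaussian chromatographic peaks,
and two-phase (lag/propagation) kinetic traces — and exports its ground
truth so every downstream stage can be tested without instrument data.
The same seed always reproduces the same outputs byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import LipidSpecies, adduct_mz, parse_lipid_name, species_formula
from .identification import (
    CentroidSpectrum,
    predict_fragments,
    theoretical_isotope_envelope,
)
from .quantification import Transition
from .kinetics import KineticTrace
from .tables import LipidomeTable

__all__ = [
    "SimulationConfig",
    "simulate_lipidome",
    "simulate_oxidized_spectra",
    "simulate_prm_run",
    "simulate_kinetic_trace",
    "simulate_kmd_rt_series",
    "default_parent_panel",
    "run_identification_benchmark",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by the generators; defaults define the standard
    study-like conditions used throughout the test-suite benchmarks."""

    seed: int = 1
    # lipidome
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"WT": 4, "KO": 4})
    features_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"TG": 30, "CE": 12, "PC": 20, "PE": 15,
                                 "LPC": 6, "SM": 8, "Cer": 6})
    log_mu: float = 14.0        # natural-log intensity location
    log_sigma: float = 1.5      # between-feature spread
    sample_cv: float = 0.20     # within-feature biological CV
    # spectra
    fragment_fraction: float = 0.9
    n_noise_peaks: int = 20
    noise_rel_intensity: float = 0.05   # of fragment base intensity
    mz_jitter_ppm: float = 3.0
    precursor_intensity: float = 1e5
    # chromatography
    peak_sigma_min: float = 0.10        # Gaussian sigma, min
    rt_step_min: float = 0.02
    response_per_amount: float = 1e6    # area units per amount unit
    snr: float | None = None            # None = noiseless
    # kinetics
    lag_s: float = 10_000.0
    baseline_slope: float = 0.005       # a.u./s during the lag phase
    propagation_slope: float = 0.10     # a.u./s after the lag
    kinetic_noise_sd: float = 0.0
    duration_s: float = 20_000.0
    n_time_points: int = 400


# ---------------------------------------------------------------------------
# lipidome tables

_CLASS_LOG_OFFSET = {"TG": 1.5, "CE": 0.8, "PC": 1.0, "PE": 0.5,
                     "LPC": -0.5, "LPE": -0.8, "PS": 0.0, "PI": 0.0,
                     "PG": -0.5, "SM": 0.2, "Cer": -0.3}


def _feature_names(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    names: list[str] = []
    for cls, n in config.features_per_class.items():
        made = set()
        while len(made) < n:
            if cls == "TG":
                c = int(rng.integers(24, 30)) * 2
                d = int(rng.integers(0, 9))
            elif cls == "CE":
                c = int(rng.integers(8, 12)) * 2
                d = int(rng.integers(0, 7))
            elif cls in ("SM", "Cer"):
                c = 18 + int(rng.integers(7, 13)) * 2
                d = 1 + int(rng.integers(0, 2))
            else:
                c = int(rng.integers(15, 21)) * 2
                d = int(rng.integers(0, 7))
            name = f"{cls} {c}:{d}"
            if name not in made:
                made.add(name)
                names.append(name)
    return names


def simulate_lipidome(
    config: SimulationConfig | None = None,
    effects: Mapping[str, float] | None = None,
    n_effect_features: int = 0,
    effect_fold_change: float = 4.0,
) -> tuple[LipidomeTable, pd.Series]:
    """A raw lipidome intensity table with known multiplicative effects.

    Intensities are log-normal per feature with class-specific location;
    fold changes (``effects`` feature->FC, or ``n_effect_features``
    random features at ``effect_fold_change``) multiply every sample of
    the *last* group.  Returns the table and the true-fold-change series
    (1.0 for unaffected features).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    names = _feature_names(config, rng)

    samples, group_labels = [], []
    for g, n in config.group_sizes.items():
        for i in range(n):
            samples.append(f"{g}_{i + 1}")
            group_labels.append(g)
    groups = pd.Series(group_labels, index=samples)
    affected_group = list(config.group_sizes)[-1]

    true_fc = pd.Series(1.0, index=names)
    if effects is None and n_effect_features > 0:
        picks = rng.choice(len(names), size=min(n_effect_features, len(names)),
                           replace=False)
        effects = {names[i]: effect_fold_change for i in picks}
    for feat, fc in (effects or {}).items():
        true_fc[feat] = fc

    sigma_within = np.sqrt(np.log1p(config.sample_cv ** 2))
    data = np.empty((len(names), len(samples)))
    for i, name in enumerate(names):
        cls = name.split(" ")[0]
        mu = config.log_mu + _CLASS_LOG_OFFSET.get(cls, 0.0) + rng.normal(0, config.log_sigma)
        base = np.exp(mu + rng.normal(0.0, sigma_within, size=len(samples)))
        fc = true_fc[name]
        if fc != 1.0:
            mask = np.array([g == affected_group for g in group_labels])
            base[mask] *= fc
        data[i] = base
    table = LipidomeTable(pd.DataFrame(data, index=names, columns=samples), groups)
    return table, true_fc


# ---------------------------------------------------------------------------
# MS/MS spectra


def default_parent_panel() -> list[LipidSpecies]:
    """Chain-resolved unsaturated neutral-lipid parents used by the
    identification benchmark."""
    names = [
        "TG 16:0/18:1/18:2", "TG 18:1/18:1/18:2", "TG 16:0/18:2/20:4",
        "TG 18:0/18:1/20:4", "TG 18:1/18:2/18:2", "TG 16:0/16:0/18:2",
        "TG 18:0/18:2/22:6", "TG 16:0/18:1/22:6",
        "CE 18:2", "CE 20:4", "CE 22:6", "CE 18:1",
    ]
    return [parse_lipid_name(n) for n in names]


def simulate_oxidized_spectra(
    species: Sequence[LipidSpecies],
    config: SimulationConfig | None = None,
    n_true: int = 200,
    n_decoy: int = 200,
    evidence: str = "retaining",
) -> tuple[list[CentroidSpectrum], list[LipidSpecies | None]]:
    """Centroided MS/MS spectra with ground-truth labels.

    True spectra contain ``fragment_fraction`` of the predicted
    fragments of one oxidized candidate (m/z jittered within
    ``mz_jitter_ppm``), low-level noise peaks, and a realistic precursor
    isotope envelope.  Decoy spectra reuse a candidate's precursor but
    shuffle the fragment m/z values so no prediction matches.  With
    ``evidence="nonretaining"`` the true spectra contain only fragments
    that shed every added oxygen (water losses of hydroxyl acyls, acyl
    losses): structurally matchable but failing the oxidized-fragment
    evidence rule.

    Returns (spectra, labels); the label is the true species or None for
    decoys.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    spectra: list[CentroidSpectrum] = []
    labels: list[LipidSpecies | None] = []

    def jitter(mz: float) -> float:
        return mz * (1.0 + rng.normal(0, config.mz_jitter_ppm / 3) * 1e-6)

    for k in range(n_true + n_decoy):
        sp = species[int(rng.integers(len(species)))]
        adduct = "[M+Na]+" if sp.lipid_class in ("TG", "DG", "CE") else "[M-H]-"
        polarity = "positive" if adduct == "[M+Na]+" else "negative"
        prec = adduct_mz(species_formula(sp), adduct)
        frags = predict_fragments(sp, adduct, polarity)
        if evidence == "nonretaining":
            frags = [f for f in frags if not f.retains_added_oxygen]
        is_true = k < n_true

        frag_mz = np.array([f.mz for f in frags])
        n_keep = max(int(round(config.fragment_fraction * frag_mz.size)), 1)
        keep = rng.choice(frag_mz.size, size=n_keep, replace=False)
        peaks = [
            (jitter(frag_mz[j]), float(rng.uniform(500, 1000))) for j in keep
        ]
        if not is_true:
            # decoy: permute fragment intensities onto random m/z within
            # the fragment mass range, destroying every match
            lo, hi = frag_mz.min() * 0.8, frag_mz.max() * 1.05
            peaks = [(float(rng.uniform(lo, hi)), inten) for _, inten in peaks]
        for _ in range(config.n_noise_peaks):
            peaks.append((
                float(rng.uniform(150.0, prec)),
                float(rng.uniform(5, 1000 * config.noise_rel_intensity)),
            ))
        env = theoretical_isotope_envelope(species_formula(sp))
        env = env * (1 + rng.normal(0, 0.02, size=env.size))
        spectra.append(CentroidSpectrum(
            precursor_mz=jitter(prec),
            rt=float(rng.uniform(5, 35)),
            polarity=polarity,
            peaks=tuple(peaks),
            precursor_intensity=config.precursor_intensity,
            precursor_isotopes=tuple(np.abs(env)),
            spectrum_id=f"scan_{k:05d}",
        ))
        labels.append(sp if is_true else None)
    return spectra, labels


def run_identification_benchmark(
    candidates: Sequence[LipidSpecies] | None = None,
    config: SimulationConfig | None = None,
    n_true: int = 200,
    n_decoy: int = 200,
    settings=None,
) -> dict:
    """Generate the true+decoy spectrum benchmark and score the full
    identification chain (match -> oxidized-fragment evidence filter).

    A call is a true positive when the top accepted candidate shares the
    true species' elemental formula (exact isomers are indistinguishable
    by mass spectrometry and are collapsed by the workflow), a false
    positive when a decoy spectrum or a wrong formula is accepted, and a
    false negative when a true spectrum yields no accepted candidate.
    """
    from .epilipidome import enumerate_oxidized_species
    from .identification import match_spectrum, oxfa_evidence_filter

    if candidates is None:
        candidates = []
        for parent in default_parent_panel():
            candidates.extend(enumerate_oxidized_species(parent))
    config = config or SimulationConfig()
    spectra, labels = simulate_oxidized_spectra(candidates, config, n_true, n_decoy)
    tp = fp = fn = tn = 0
    for spec, label in zip(spectra, labels):
        ids = oxfa_evidence_filter(match_spectrum(spec, candidates, settings))
        accepted = [i for i in ids if i.accepted]
        top = accepted[0].species if accepted else None
        if label is None:
            if top is None:
                tn += 1
            else:
                fp += 1
        elif top is None:
            fn += 1
        elif str(species_formula(top)) == str(species_formula(label)):
            tp += 1
        else:
            fp += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": precision, "recall": recall,
            "n_candidates": len(candidates)}


# ---------------------------------------------------------------------------
# PRM runs


def simulate_prm_run(
    transitions: Sequence[Transition],
    amounts: Mapping[str, float],
    config: SimulationConfig | None = None,
) -> tuple[list[CentroidSpectrum], pd.Series]:
    """A PRM run of product-ion scans with Gaussian elution profiles.

    Each transition elutes as a Gaussian of sigma ``peak_sigma_min``
    centred on its expected RT (default 10 min), with chromatographic
    area ``response_per_amount`` x amount.  With ``snr`` set, every scan
    intensity is corrupted by signal-proportional Gaussian noise of
    relative s.d. 1/snr (centroided peak intensities scale their noise
    with the signal).  Returns the scan list and the true areas per
    transition.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    scans: list[CentroidSpectrum] = []
    true_areas = {}
    for t in transitions:
        amount = float(amounts.get(t.name, 0.0))
        area = config.response_per_amount * amount
        true_areas[t.name] = area
        rt0 = t.expected_rt if t.expected_rt is not None else 10.0
        sigma = config.peak_sigma_min
        grid = np.arange(rt0 - 6 * sigma, rt0 + 6 * sigma + config.rt_step_min / 2,
                         config.rt_step_min)
        apex = area / (sigma * np.sqrt(2 * np.pi)) if area > 0 else 0.0
        profile = apex * np.exp(-0.5 * ((grid - rt0) / sigma) ** 2) if area > 0 else np.zeros_like(grid)
        if config.snr is not None and apex > 0:
            profile = profile * (1.0 + rng.normal(0, 1.0 / config.snr, size=profile.size))
            profile = np.clip(profile, 0, None)
        for rt, inten in zip(grid, profile):
            scans.append(CentroidSpectrum(
                precursor_mz=t.precursor_mz,
                rt=float(rt),
                polarity="positive",
                peaks=((t.product_mz, float(inten)),) if inten > 0 else (),
                precursor_intensity=1e6,
                ms_level=2,
                isolation_width=1.2,
                spectrum_id=f"prm_{t.name}_{rt:.3f}",
            ))
    scans.sort(key=lambda s: s.rt)
    return scans, pd.Series(true_areas)


# ---------------------------------------------------------------------------
# kinetics


def simulate_kinetic_trace(
    config: SimulationConfig | None = None,
    coupled_nadh: bool = False,
) -> tuple[KineticTrace, dict] | tuple[KineticTrace, KineticTrace, dict]:
    """A two-phase lag/propagation fluorescence trace with known lag.

    Piecewise-linear: slow baseline growth until ``lag_s``, then fast
    propagation, plus additive Gaussian noise.  With ``coupled_nadh``,
    a second channel decreases linearly during the lag and reaches zero
    exactly at the lag end (NADH exhaustion starts propagation).
    Ground truth is returned as a dict.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    t = np.linspace(0.0, config.duration_s, config.n_time_points)
    s0 = 100.0
    lag = config.lag_s
    s = np.where(
        t < lag,
        s0 + config.baseline_slope * t,
        s0 + config.baseline_slope * lag + config.propagation_slope * (t - lag),
    )
    if config.kinetic_noise_sd > 0:
        s = s + rng.normal(0, config.kinetic_noise_sd, size=s.size)
    s = np.clip(s, 0, None)
    trace = KineticTrace(t, s, "oxidized BODIPY-C11")
    truth = {"lag_s": lag, "propagation_slope": config.propagation_slope,
             "baseline_slope": config.baseline_slope}
    if coupled_nadh:
        nadh = np.clip(1000.0 * (1.0 - t / lag), 0, None) if lag > 0 else np.zeros_like(t)
        nadh_trace = KineticTrace(t, nadh, "NADH autofluorescence")
        return trace, nadh_trace, truth
    return trace, truth


# ---------------------------------------------------------------------------
# KMD-RT homologous series


def simulate_kmd_rt_series(
    seed: int = 1,
    n_inliers: int = 10,
    nominal_sigma: float = 1e-3,
    outlier_sigma_mult: float = 10.0,
    noise_sd: float = 0.0,
) -> tuple[list[tuple[LipidSpecies, float, float]], list[bool]]:
    """A CH2-homologous oxidized-TG series, collinear in KMD vs RT, plus
    one planted outlier whose KMD deviates by ``outlier_sigma_mult`` x
    ``nominal_sigma``.  Returns (entries, truth flags)."""
    rng = np.random.default_rng(seed)
    base_db = 2
    carbons = [44 + 2 * i for i in range(n_inliers + 1)]
    rt0 = float(rng.uniform(8, 12))
    rt_per_c = float(rng.uniform(0.4, 0.6))
    outlier_idx = int(rng.integers(n_inliers + 1))
    entries, truth = [], []
    for i, c in enumerate(carbons):
        sp = parse_lipid_name(f"TG {c}:{base_db}<OOH>")
        mz = adduct_mz(species_formula(sp), "[M+Na]+")
        rt = rt0 + rt_per_c * (c - carbons[0])
        if noise_sd > 0:
            # perturb m/z so the KMD moves by ~N(0, noise_sd)
            mz = mz + float(rng.normal(0, noise_sd)) * 14.01565 / 14.0
        if i == outlier_idx:
            mz = mz + outlier_sigma_mult * nominal_sigma * 14.01565 / 14.0
        entries.append((sp, mz, rt))
        truth.append(i == outlier_idx)
    return entries, truth
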