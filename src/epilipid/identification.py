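"""Rule-based identification of oxidized lipids from centroided MS/MS.

The confidence rule at the core: an identification is only accepted if
at least one matched fragment is an *oxidized fatty-acid specific
fragment* — the intact oxidized fatty acid as an adduct ion, or an
oxidized fatty-acid fragment that retains at least one of the added
oxygen atoms after fragmentation.  Fragments of an oxidized acyl that
shed every added oxygen (for example a hydroxy-acyl after water loss)
carry no modification-specific information and cannot support the call.

Score definitions are local to this package (the upstream tool's
formulas are not public): ``score`` is the fraction of considered ion
current explained by predicted fragments, ``isotope_score`` the cosine
similarity between the observed and theoretical precursor isotope
envelope over the first three isotopologues, and ``rank_score`` the mean
intensity-percentile rank of the matched peaks.  All are on a 0-100
scale and the printed acceptance thresholds (60/80/40) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    ELECTRON_MASS,
    ElementalFormula,
    FattyAcyl,
    LipidSpecies,
    ModificationSet,
    adduct_mz,
    get_adduct,
    kendrick_mass_defect,
    monoisotopic_mass,
    species_formula,
)

__all__ = [
    "CentroidSpectrum",
    "MatchSettings",
    "FragmentAnnotation",
    "Identification",
    "UnmodifiedSpecies",
    "predict_fragments",
    "match_spectrum",
    "oxfa_evidence_filter",
    "kmd_rt_filter",
    "collapse_isomers",
    "theoretical_isotope_envelope",
]

_WATER = ElementalFormula.parse("H2O")
_C13_DELTA = 1.0033548378  # 13C - 12C


class UnmodifiedSpecies(ValueError):
    """Fragment prediction applies to oxidized species only."""


@dataclass(frozen=True)
class CentroidSpectrum:
    """A centroided MS/MS spectrum with precursor annotation.

    ``precursor_isotopes``, when present, holds the survey-scan
    intensities of the first isotopologues (M, M+1, M+2) of the
    precursor, used for the isotope score.
    """

    precursor_mz: float
    rt: float
    polarity: str                       # "positive" | "negative"
    peaks: tuple[tuple[float, float], ...]
    precursor_intensity: float = 0.0
    precursor_isotopes: tuple[float, ...] | None = None
    ms_level: int = 2
    isolation_width: float = 1.2        # Th
    spectrum_id: str = ""

    def __post_init__(self):
        peaks = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in peaks):
            raise ValueError("peak intensities must be >= 0")
        object.__setattr__(self, "peaks", peaks)
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass(frozen=True)
class MatchSettings:
    """Tolerances and score thresholds for oxidized-lipid identification."""

    ms1_tol: float = 5.0            # ppm
    ms2_tol: float = 20.0           # ppm
    min_precursor_intensity: float = 100.0
    min_rel_peak_intensity: float = 0.01   # fraction of base peak
    score_min: float = 60.0
    isotope_score_min: float = 80.0
    rank_score_min: float = 40.0

    def __post_init__(self):
        if self.ms1_tol <= 0 or self.ms2_tol <= 0:
            raise ValueError("tolerances must be > 0")
        for t in (self.score_min, self.isotope_score_min, self.rank_score_min):
            if not 0 <= t <= 100:
                raise ValueError("score thresholds must lie in [0, 100]")


@dataclass(frozen=True)
class FragmentAnnotation:
    """One predicted fragment ion of an oxidized lipid candidate."""

    descriptor: str
    formula: ElementalFormula
    mz: float
    retains_added_oxygen: bool
    origin: str     # intact-oxfa | oxfa-water-loss | acyl-loss | headgroup


@dataclass(frozen=True)
class Identification:
    """A scored candidate-spectrum match with its acceptance state."""

    spectrum_id: str
    species: LipidSpecies
    adduct: str
    precursor_mz: float
    rt: float
    matched: tuple[FragmentAnnotation, ...]
    score: float
    isotope_score: float
    rank_score: float
    accepted: bool
    reasons: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# fragment prediction


def _chain_ion(chain: FattyAcyl, adduct_name: str, waters_lost: int) -> tuple[ElementalFormula, float, bool]:
    """Formula, m/z and oxygen retention of a (possibly dehydrated)
    free-fatty-acid fragment ion.

    Oxygen retention is decided by formula accounting: the fragment
    retains added oxygen iff its oxygen count exceeds that of the same
    fragment built from the unmodified acyl.
    """
    free = FattyAcyl(chain.carbons, chain.double_bonds, "acyl", chain.modifications)
    f = free.free_formula()
    for _ in range(waters_lost):
        f = f - _WATER
    # water loss is attributed to the modification oxygens (the
    # carboxyl group survives), so the fragment keeps an added oxygen
    # iff its oxygen count still exceeds that of the unmodified acid
    unmod = FattyAcyl(chain.carbons, chain.double_bonds, "acyl").free_formula()
    retains = chain.modifications.total_groups > 0 and f["O"] > unmod["O"]
    return f, adduct_mz(f, adduct_name), retains


def _chain_descriptor(chain: FattyAcyl, suffix: str) -> str:
    mods = chain.modifications.shorthand()
    return f"[FA{chain.carbons}:{chain.double_bonds}{mods}{suffix}"


def predict_fragments(
    species: LipidSpecies,
    adduct: str | None = None,
    polarity: str | None = None,
) -> list[FragmentAnnotation]:
    """Diagnostic fragments of an oxidized neutral or polar lipid.

    Positive sodiated oxTG/oxCE: intact [oxFA+Na]+ and [oxFA+H]+, their
    water losses, the neutral loss of each acyl (as free acid) from the
    precursor, and class headgroup diagnostics.  Negative-mode oxPC/oxPE:
    [oxFA-H]- and its water loss.  Each annotation carries
    ``retains_added_oxygen`` computed from its formula.
    """
    if not species.is_oxidized:
        raise UnmodifiedSpecies(f"{species} carries no oxidation modification")
    if species.chains is None:
        raise UnmodifiedSpecies(
            f"{species} is a sum composition without resolved chains; "
            "fragment prediction needs chain-level composition"
        )
    cls = species.lipid_class
    if polarity is None:
        polarity = "positive" if cls in ("TG", "DG", "CE") else "negative"
    if adduct is None:
        adduct = "[M+Na]+" if polarity == "positive" else "[M-H]-"
    adduct = get_adduct(adduct).name

    out: list[FragmentAnnotation] = []
    precursor_f = species_formula(species)

    if polarity == "positive":
        ion_tags = [("+Na]+", "[M+Na]+"), ("+H]+", "[M+H]+")]
    else:
        ion_tags = [("-H]-", "[M-H]-")]

    for chain in species.chains:
        if not chain.modifications:
            continue
        for suffix, frag_adduct in ion_tags:
            f, mz, retains = _chain_ion(chain, frag_adduct, waters_lost=0)
            out.append(FragmentAnnotation(
                _chain_descriptor(chain, suffix), f, mz, retains, "intact-oxfa"))
            f, mz, retains = _chain_ion(chain, frag_adduct, waters_lost=1)
            out.append(FragmentAnnotation(
                _chain_descriptor(chain, "-H2O" + suffix), f, mz, retains,
                "oxfa-water-loss"))

    if polarity == "positive":
        # neutral loss of each acyl chain (as the free acid) from the precursor
        for chain in species.chains:
            if chain.bond_type != "acyl":
                continue
            loss = FattyAcyl(chain.carbons, chain.double_bonds, "acyl",
                             chain.modifications).free_formula()
            try:
                residual = precursor_f - loss
            except ValueError:
                continue
            mz = adduct_mz(residual, adduct)
            tag = "+Na]+" if "Na" in adduct else "+H]+"
            chain_name = f"FA{chain.carbons}:{chain.double_bonds}{chain.modifications.shorthand()}"
            out.append(FragmentAnnotation(
                f"[M-{chain_name}{tag}", residual, mz, False, "acyl-loss"))
        if cls == "CE":
            # cholestadiene cation, the steryl-ester headgroup diagnostic
            chol = ElementalFormula.parse("C27H44")
            mz = monoisotopic_mass(chol) + monoisotopic_mass(ElementalFormula.parse("H")) - ELECTRON_MASS
            out.append(FragmentAnnotation("[Chol-H2O+H]+", chol, mz, False, "headgroup"))

    # dedup identical (descriptor, mz)
    seen = set()
    uniq = []
    for a in out:
        key = (a.descriptor, round(a.mz, 6))
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    return uniq


# ---------------------------------------------------------------------------
# isotope envelope


def theoretical_isotope_envelope(formula: ElementalFormula, n: int = 3) -> np.ndarray:
    """Approximate relative intensities of the first ``n`` isotopologues.

    Poisson-style approximation from heavy-isotope abundances (13C
    1.07%, 2H 0.0156%, 15N 0.364%, 18O 0.205%); adequate for a cosine
    comparison over three isotopologues.
    """
    lam1 = (formula["C"] * 0.0107 + formula["H"] * 0.000156 + formula["N"] * 0.00364)
    a2_extra = formula["O"] * 0.00205 + formula["S"] * 0.0443 if formula["S"] else formula["O"] * 0.00205
    env = [1.0, lam1, lam1 ** 2 / 2 + a2_extra]
    return np.array(env[:n])


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# matching


def _ppm(a: float, b: float) -> float:
    return abs(a - b) / b * 1e6


def _score_candidate(
    spectrum: CentroidSpectrum,
    fragments: Sequence[FragmentAnnotation],
    settings: MatchSettings,
) -> tuple[list[FragmentAnnotation], float, float, float]:
    mz = spectrum.mz_array
    inten = spectrum.intensity_array
    if mz.size == 0:
        return [], 0.0, 0.0, 0.0
    base = inten.max()
    considered = inten >= settings.min_rel_peak_intensity * base
    cm, ci = mz[considered], inten[considered]
    if cm.size == 0:
        return [], 0.0, 0.0, 0.0

    matched: list[FragmentAnnotation] = []
    matched_peaks: set[int] = set()
    for frag in fragments:
        d = np.abs(cm - frag.mz) / frag.mz * 1e6
        j = int(np.argmin(d))
        if d[j] <= settings.ms2_tol:
            matched.append(frag)
            matched_peaks.add(j)

    total = float(ci.sum())
    explained = float(ci[sorted(matched_peaks)].sum()) if matched_peaks else 0.0
    score = 100.0 * explained / total if total > 0 else 0.0

    # rank score: mean percentile rank of matched peak intensities
    if matched_peaks and cm.size > 1:
        order = np.argsort(np.argsort(ci))  # 0 = weakest
        ranks = order[sorted(matched_peaks)] / (cm.size - 1)
        rank_score = 100.0 * float(ranks.mean())
    elif matched_peaks:
        rank_score = 100.0
    else:
        rank_score = 0.0
    return matched, score, 0.0, rank_score


def match_spectrum(
    spectrum: CentroidSpectrum,
    candidates: Sequence[LipidSpecies],
    settings: MatchSettings | None = None,
) -> list[Identification]:
    """Score oxidized-lipid candidates against one MS/MS spectrum.

    A candidate enters scoring only if its precursor adduct m/z lies
    within ``ms1_tol`` of the spectrum precursor and the precursor
    intensity clears the floor.  Scores are deterministic and candidate-
    order invariant; results are sorted by descending score, name.
    """
    settings = settings or MatchSettings()
    out: list[Identification] = []
    if spectrum.precursor_intensity < settings.min_precursor_intensity:
        return out
    for sp in candidates:
        cls = sp.lipid_class
        polarity = "positive" if cls in ("TG", "DG", "CE") else "negative"
        if polarity != spectrum.polarity:
            continue
        adduct = "[M+Na]+" if polarity == "positive" else "[M-H]-"
        prec_mz = adduct_mz(species_formula(sp), adduct)
        if _ppm(spectrum.precursor_mz, prec_mz) > settings.ms1_tol:
            continue
        fragments = predict_fragments(sp, adduct, polarity)
        matched, score, _, rank_score = _score_candidate(spectrum, fragments, settings)

        if spectrum.precursor_isotopes is not None:
            theo = theoretical_isotope_envelope(species_formula(sp))
            obs = np.asarray(spectrum.precursor_isotopes, dtype=float)[: theo.size]
            iso_score = 100.0 * _cosine(theo[: obs.size], obs)
        else:
            iso_score = 100.0  # no envelope information: pass-through

        reasons = []
        if score <= settings.score_min:
            reasons.append("score")
        if iso_score <= settings.isotope_score_min:
            reasons.append("isotope_score")
        if rank_score <= settings.rank_score_min:
            reasons.append("rank_score")
        out.append(Identification(
            spectrum_id=spectrum.spectrum_id,
            species=sp,
            adduct=adduct,
            precursor_mz=spectrum.precursor_mz,
            rt=spectrum.rt,
            matched=tuple(matched),
            score=score,
            isotope_score=iso_score,
            rank_score=rank_score,
            accepted=not reasons,
            reasons=tuple(reasons),
        ))
    out.sort(key=lambda i: (-i.score, i.species.name()))
    return out


def oxfa_evidence_filter(ids: Iterable[Identification]) -> list[Identification]:
    """Retain only identifications evidenced by an oxidized fatty-acid
    specific fragment (one that keeps >= 1 added oxygen); others are
    marked rejected with reason ``no_oxfa_fragment``."""
    out = []
    for ident in ids:
        has_oxfa = any(a.retains_added_oxygen for a in ident.matched)
        if has_oxfa:
            out.append(ident)
        else:
            out.append(replace(
                ident, accepted=False,
                reasons=tuple(ident.reasons) + ("no_oxfa_fragment",),
            ))
    return out


# ---------------------------------------------------------------------------
# KMD-RT false-positive filter


def _lad_fit(x: np.ndarray, y: np.ndarray, iters: int = 50) -> tuple[float, float]:
    """Least-absolute-deviations line via iteratively reweighted least
    squares; adequate and dependency-free for 2 parameters."""
    slope, intercept = np.polyfit(x, y, 1)
    for _ in range(iters):
        r = np.abs(y - slope * x - intercept)
        w = 1.0 / np.maximum(r, 1e-12)
        W = np.sqrt(w)
        A = np.column_stack([x * W, W])
        coef, *_ = np.linalg.lstsq(A, y * W, rcond=None)
        if np.allclose([slope, intercept], coef, rtol=0, atol=1e-14):
            break
        slope, intercept = coef
    return float(slope), float(intercept)


def kmd_rt_filter(
    entries: Sequence[tuple[LipidSpecies, float, float]],
    residual_threshold: float = 3.0,
    min_group_size: int = 3,
) -> list[bool]:
    """Flag false-positive annotations that break the linear Kendrick
    mass defect vs retention time trend of their homologous series.

    Entries are (species, m/z, RT).  Series are grouped by (class, ether
    subclass, pooled modification set, double-bond count); within each
    group of >= ``min_group_size`` an LAD line of KMD on RT is fitted and
    members whose MAD-studentized residual exceeds the threshold are
    flagged (True = false positive).  Smaller groups pass unflagged.
    """
    flags = [False] * len(entries)
    groups: dict[tuple, list[int]] = {}
    for i, (sp, mz, rt) in enumerate(entries):
        mods = sp.all_modifications
        key = (sp.lipid_class, sp.ether,
               (mods.n_OH, mods.n_oxo, mods.n_OOH, mods.n_epoxy),
               sp.total_double_bonds)
        groups.setdefault(key, []).append(i)

    for idx in groups.values():
        if len(idx) < min_group_size:
            continue
        rt = np.array([entries[i][2] for i in idx])
        kmd = np.array([kendrick_mass_defect(entries[i][1])[1] for i in idx])
        slope, intercept = _lad_fit(rt, kmd)
        resid = kmd - (slope * rt + intercept)
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = max(1.4826 * mad, 1e-9)
        for i, r in zip(idx, resid):
            if abs(r) / scale > residual_threshold:
                flags[i] = True
    return flags


def collapse_isomers(
    ids: Sequence[Identification], mz_tol_ppm: float = 5.0
) -> list[Identification]:
    """Merge identifications that are isomeric at the precursor level
    (within ``mz_tol_ppm``), keeping the highest-scoring representative
    per distinct m/z."""
    ordered = sorted(ids, key=lambda i: i.precursor_mz)
    clusters: list[list[Identification]] = []
    for ident in ordered:
        if clusters and _ppm(ident.precursor_mz, clusters[-1][0].precursor_mz) <= mz_tol_ppm:
            clusters[-1].append(ident)
        else:
            clusters.append([ident])
    return [max(cl, key=lambda i: (i.score, i.species.name())) for cl in clusters]
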