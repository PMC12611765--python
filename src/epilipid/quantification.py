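"""XIC extraction, peak integration, PRM relative quantification,
isotope-dilution absolute quantification and CoQ redox metrics.

Quantification is deliberately rule-based and deterministic: XICs are
built per scan by summing centroided peaks within a symmetric ppm
tolerance of the target, peaks are integrated by the trapezoid rule
above a linear baseline drawn between the integration-window endpoints,
and PRM transitions restrict the product-ion XIC to scans whose
isolation window contains the precursor.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .chem import ElementalFormula, adduct_mz, get_adduct
from .identification import CentroidSpectrum

__all__ = [
    "Chromatogram",
    "Transition",
    "InternalStandardMap",
    "EmptyWindow",
    "ZeroStandardArea",
    "extract_xic",
    "integrate_peak",
    "prm_quantify",
    "normalize_to_internal_standard",
    "normalize_to_protein",
    "isotope_dilution_amount",
    "coq_redox_metrics",
    "CalibrationModel",
    "external_calibration",
    "back_calculate",
    "quinone_transitions",
]


class EmptyWindow(ValueError):
    """Integration window contains no chromatogram points."""


class ZeroStandardArea(ValueError):
    """Isotope dilution needs a positive standard area."""


@dataclass(frozen=True)
class Chromatogram:
    """An extracted ion chromatogram."""

    rt: np.ndarray
    intensity: np.ndarray
    target_mz: float
    tol_ppm: float

    def __post_init__(self):
        rt = np.asarray(self.rt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if rt.shape != inten.shape:
            raise ValueError("RT and intensity arrays must have equal length")
        if rt.size > 1 and not np.all(np.diff(rt) > 0):
            raise ValueError("RT must be strictly increasing")
        if (inten < 0).any():
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class Transition:
    """A precursor -> product pair quantified from PRM scans."""

    name: str
    precursor_mz: float
    product_mz: float
    precursor_adduct: str = "[M+NH4]+"
    product_adduct: str = "[M+H]+"
    expected_rt: float | None = None     # min
    collision_energy: float | None = None
    tol_ppm: float = 5.0

    def __post_init__(self):
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be positive")


@dataclass(frozen=True)
class InternalStandardMap:
    """Per-lipid-class internal standards: class -> (standard feature
    name, spiked amount).  Classes listed in ``unnormalized`` are
    explicitly passed through without normalization."""

    standards: Mapping[str, tuple[str, float]]
    unnormalized: frozenset[str] = frozenset()


def extract_xic(
    run: Sequence[CentroidSpectrum], target_mz: float, tol_ppm: float = 5.0
) -> Chromatogram:
    """Per-scan summed intensity of centroided peaks within +-tol ppm of
    the target m/z; scans with no matching peak contribute zero."""
    rts, ints = [], []
    half = target_mz * tol_ppm * 1e-6
    for scan in sorted(run, key=lambda s: s.rt):
        mz = scan.mz_array
        inten = scan.intensity_array
        sel = (mz >= target_mz - half) & (mz <= target_mz + half)
        rts.append(scan.rt)
        ints.append(float(inten[sel].sum()) if mz.size else 0.0)
    return Chromatogram(np.array(rts), np.array(ints), target_mz, tol_ppm)


def integrate_peak(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """Trapezoidal area above a linear endpoint baseline, clamped >= 0."""
    lo, hi = window
    if not lo < hi:
        raise EmptyWindow(f"bad RT window {window}")
    sel = (chrom.rt >= lo) & (chrom.rt <= hi)
    if sel.sum() < 2:
        raise EmptyWindow(f"window {window} spans < 2 chromatogram points")
    rt = chrom.rt[sel]
    y = chrom.intensity[sel]
    baseline = np.interp(rt, [rt[0], rt[-1]], [y[0], y[-1]])
    area = float(np.trapezoid(y - baseline, rt))
    return max(area, 0.0)


def prm_quantify(
    run: Sequence[CentroidSpectrum],
    transitions: Sequence[Transition],
    rt_half_window: float = 0.5,
) -> pd.DataFrame:
    """Integrated product-ion XIC area per transition.

    Only MS2 scans whose isolation window contains the transition
    precursor are used.  Transitions without any matching scan are
    flagged (``matched_scans`` 0, area NaN) rather than failing the run.
    Integration uses ``expected_rt`` +- ``rt_half_window`` when an
    expected RT is given, else the full acquired range.
    """
    rows = []
    for t in transitions:
        scans = [
            s for s in run
            if s.ms_level == 2
            and abs(s.precursor_mz - t.precursor_mz) <= s.isolation_width / 2
        ]
        if not scans:
            rows.append({"transition": t.name, "area": np.nan,
                         "matched_scans": 0, "flag": "no_matching_isolation"})
            continue
        chrom = extract_xic(scans, t.product_mz, t.tol_ppm)
        if t.expected_rt is not None:
            window = (t.expected_rt - rt_half_window, t.expected_rt + rt_half_window)
            lo = max(window[0], chrom.rt[0])
            hi = min(window[1], chrom.rt[-1])
        else:
            lo, hi = chrom.rt[0], chrom.rt[-1]
        try:
            area = integrate_peak(chrom, (lo, hi))
            flag = ""
        except EmptyWindow:
            area, flag = np.nan, "empty_window"
        rows.append({"transition": t.name, "area": area,
                     "matched_scans": len(scans), "flag": flag})
    return pd.DataFrame(rows).set_index("transition")


def normalize_to_internal_standard(
    areas: pd.DataFrame,
    feature_classes: Mapping[str, str],
    is_map: InternalStandardMap,
    standard_areas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Divide each analyte's areas by its class internal-standard areas.

    ``areas``: features x samples.  ``standard_areas`` defaults to rows
    of ``areas`` named like the mapped standards.  A feature whose class
    has no mapping (and is not explicitly unnormalized) is an error.
    """
    std = standard_areas if standard_areas is not None else areas
    out = {}
    for feat in areas.index:
        cls = feature_classes.get(feat)
        if cls in is_map.unnormalized:
            out[feat] = areas.loc[feat]
            continue
        if cls is None or cls not in is_map.standards:
            raise KeyError(f"no internal standard mapped for class {cls!r} (feature {feat!r})")
        std_name, _amount = is_map.standards[cls]
        if std_name not in std.index:
            raise KeyError(f"standard {std_name!r} absent from the area table")
        out[feat] = areas.loc[feat] / std.loc[std_name]
    return pd.DataFrame(out).T.loc[areas.index]


def normalize_to_protein(table: pd.DataFrame, protein: pd.Series) -> pd.DataFrame:
    """Per-sample division by protein concentration (units propagate as
    value per mg); zero or negative protein is an error."""
    protein = protein.reindex(table.columns)
    if protein.isna().any():
        raise ValueError("protein concentration missing for some samples")
    if (protein <= 0).any():
        raise ValueError("protein concentrations must be > 0")
    return table.div(protein, axis=1)


def isotope_dilution_amount(
    analyte_area: float, standard_area: float, standard_amount: float
) -> float:
    """Absolute amount by isotope dilution: analyte area divided by the
    co-analysed labelled-standard area, times the spiked amount."""
    if standard_area <= 0:
        raise ZeroStandardArea("labelled-standard area must be > 0")
    return analyte_area / standard_area * standard_amount


@dataclass(frozen=True)
class CoQRedoxMetrics:
    total: float
    fraction_reduced: float
    coq_per_neutral_lipid: float


def coq_redox_metrics(
    amount_coq10: float, amount_coq10h2: float, neutral_lipid_amount: float
) -> CoQRedoxMetrics:
    """Total CoQ10 pool, reduced (ubiquinol) fraction, and the
    CoQ-per-neutral-lipid mole ratio."""
    total = amount_coq10 + amount_coq10h2
    if total <= 0:
        raise ValueError("total CoQ10 amount must be > 0 for redox metrics")
    if neutral_lipid_amount <= 0:
        raise ValueError("neutral lipid amount must be > 0")
    return CoQRedoxMetrics(
        total=total,
        fraction_reduced=amount_coq10h2 / total,
        coq_per_neutral_lipid=total / neutral_lipid_amount,
    )


@dataclass(frozen=True)
class CalibrationModel:
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]


def external_calibration(points: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Least-squares line response = slope * conc + intercept from
    (known concentration, response) pairs; >= 2 distinct levels needed."""
    conc = np.array([p[0] for p in points], dtype=float)
    resp = np.array([p[1] for p in points], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("calibration needs >= 2 distinct concentration levels")
    res = _sps.linregress(conc, resp)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def back_calculate(model: CalibrationModel, response: float) -> tuple[float, bool]:
    """Invert the calibration; returns (concentration, extrapolated?)."""
    if model.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    conc = (response - model.intercept) / model.slope
    extrapolated = not (model.conc_range[0] <= conc <= model.conc_range[1])
    return conc, extrapolated


def quinone_transitions() -> pd.DataFrame:
    """The packaged PRM transition table for the redox-active lipids
    (CoQ8/9/10 and their quinols, CoQ10-d6, vitamin K1, menaquinone-4,
    alpha-tocopherol), with all m/z recomputed from the elemental
    formulas at load time."""
    path = importlib.resources.files("epilipid.data") / "quinone_transitions.csv"
    df = pd.read_csv(path)
    convention = {
        name: conv for name, conv in zip(df["name"], df["electron_convention"])
    }
    df["precursor_mz"] = [
        adduct_mz(ElementalFormula.parse(f), a)
        for f, a in zip(df["precursor_formula"], df["precursor_adduct"])
    ]
    df["product_mz"] = [
        adduct_mz(ElementalFormula.parse(f), a, convention[n])
        for n, f, a in zip(df["name"], df["product_formula"], df["product_adduct"])
    ]
    return df
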