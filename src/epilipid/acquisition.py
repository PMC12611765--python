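"""Inclusion lists for predicted oxidized precursors and iterative
exclusion lists for deep DDA profiling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chem import Adduct, LipidSpecies, adduct_mz, get_adduct, species_formula

__all__ = [
    "InclusionEntry",
    "ExclusionEntry",
    "IterativeExclusionParams",
    "build_inclusion_list",
    "build_iterative_exclusion_list",
]


@dataclass(frozen=True)
class InclusionEntry:
    mz: float
    polarity: str             # "positive" | "negative"
    adduct: str
    species: str = ""
    rt_start: float | None = None
    rt_stop: float | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.rt_start is not None and self.rt_stop is not None:
            if not self.rt_start < self.rt_stop:
                raise ValueError("RT start must precede RT stop")


@dataclass(frozen=True)
class ExclusionEntry:
    mz: float
    mz_window: float
    rt: float
    rt_window: float

    @property
    def mz_range(self) -> tuple[float, float]:
        return self.mz - self.mz_window, self.mz + self.mz_window

    @property
    def rt_range(self) -> tuple[float, float]:
        return self.rt - self.rt_window, self.rt + self.rt_window


@dataclass(frozen=True)
class IterativeExclusionParams:
    """Parameters for exclusion-list generation from a prior DDA run.

    ``noise_count`` sets the noise floor as the intensity of the
    noise_count-th weakest retained precursor; only precursors strictly
    above the floor are excluded in the following run.
    """

    rt_window: float = 0.3    # min
    noise_count: int = 15
    mz_window: float = 0.02   # Th
    max_rt: float = 36.0      # min

    def __post_init__(self):
        if min(self.rt_window, self.noise_count, self.mz_window, self.max_rt) <= 0:
            raise ValueError("all iterative-exclusion parameters must be > 0")


def build_inclusion_list(
    species: Sequence[LipidSpecies],
    adducts: Sequence[Adduct | str] = ("[M+Na]+",),
    dedup_ppm: float = 5.0,
) -> list[InclusionEntry]:
    """One entry per (species, adduct), deduplicated at ``dedup_ppm``
    (isomeric species collapse to a single m/z), sorted by m/z."""
    entries = []
    for sp in species:
        f = species_formula(sp)
        for ad in adducts:
            ad = get_adduct(ad) if isinstance(ad, str) else ad
            entries.append(
                InclusionEntry(
                    mz=adduct_mz(f, ad),
                    polarity="positive" if ad.charge > 0 else "negative",
                    adduct=ad.name,
                    species=sp.name(),
                )
            )
    entries.sort(key=lambda e: e.mz)
    deduped: list[InclusionEntry] = []
    for e in entries:
        if deduped and e.polarity == deduped[-1].polarity and (
            abs(e.mz - deduped[-1].mz) / deduped[-1].mz * 1e6 <= dedup_ppm
        ):
            continue
        deduped.append(e)
    return deduped


def build_iterative_exclusion_list(
    prior_run: Iterable[tuple[float, float, float]],
    params: IterativeExclusionParams | None = None,
) -> list[ExclusionEntry]:
    """Exclusion entries for precursors already fragmented in a prior run.

    ``prior_run`` yields (m/z, RT min, intensity) records.  Precursors
    past ``max_rt`` are dropped; the weakest ``noise_count`` signals
    define the noise floor; survivors within ``mz_window`` and
    ``rt_window`` of each other merge into one entry (intensity-weighted
    centroid).
    """
    params = params or IterativeExclusionParams()
    records = [
        (mz, rt, inten) for mz, rt, inten in prior_run if rt <= params.max_rt
    ]
    if not records:
        return []
    intensities = sorted(r[2] for r in records)
    k = min(params.noise_count, len(intensities)) - 1
    floor = intensities[k] if len(intensities) > params.noise_count else -np.inf
    kept = [r for r in records if r[2] > floor]

    kept.sort(key=lambda r: (r[0], r[1]))
    clusters: list[list[tuple[float, float, float]]] = []
    for rec in kept:
        placed = False
        for cl in clusters:
            mz_c = sum(m * i for m, _, i in cl) / sum(i for *_, i in cl)
            rt_c = sum(t * i for _, t, i in cl) / sum(i for *_, i in cl)
            if abs(rec[0] - mz_c) <= params.mz_window and abs(rec[1] - rt_c) <= params.rt_window:
                cl.append(rec)
                placed = True
                break
        if not placed:
            clusters.append([rec])

    out = []
    for cl in clusters:
        w = sum(i for *_, i in cl)
        mz_c = sum(m * i for m, _, i in cl) / w
        rt_c = sum(t * i for _, t, i in cl) / w
        out.append(ExclusionEntry(mz=mz_c, mz_window=params.mz_window,
                                  rt=rt_c, rt_window=params.rt_window))
    out.sort(key=lambda e: e.mz)
    return out
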