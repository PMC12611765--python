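"""Readers and writers for the formats the pipeline consumes and emits.

Spectra come in as centroided mzML (parsed by a compact internal reader
covering the subset standard converters emit) or as the package's
documented JSON peak-list format::

    {"spectra": [
        {"precursor_mz": 899.73, "precursor_intensity": 1e5,
         "rt": 12.3, "polarity": "positive",
         "peaks": [[mz, intensity], ...],
         "precursor_isotopes": [1.0, 0.64, 0.22],   # optional
         "ms_level": 2, "isolation_width": 1.2,      # optional
         "id": "scan_00001"}, ...]}

Tables travel as CSV/TSV; lipidome tables carry their group labels in a
first row whose index is ``group``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .acquisition import ExclusionEntry, InclusionEntry
from .identification import CentroidSpectrum, Identification
from .kinetics import KineticTrace
from .quantification import Transition
from .tables import LipidomeTable

__all__ = [
    "UnsupportedFormat",
    "ProfileModeData",
    "read_spectra",
    "write_spectra_json",
    "read_lipidome_csv",
    "write_lipidome_csv",
    "write_inclusion_csv",
    "write_exclusion_csv",
    "read_transitions_csv",
    "read_kinetic_traces_csv",
    "write_identifications_tsv",
]


class UnsupportedFormat(ValueError):
    """File is neither mzML nor the JSON peak-list format."""


class ProfileModeData(ValueError):
    """Profile-mode spectra cannot be used; centroid the data first."""


def _spectrum_from_dict(d: dict, fallback_id: str) -> CentroidSpectrum:
    return CentroidSpectrum(
        precursor_mz=float(d["precursor_mz"]),
        rt=float(d["rt"]),
        polarity=d["polarity"],
        peaks=tuple((float(m), float(i)) for m, i in d["peaks"]),
        precursor_intensity=float(d.get("precursor_intensity", 0.0)),
        precursor_isotopes=(
            tuple(float(x) for x in d["precursor_isotopes"])
            if d.get("precursor_isotopes") is not None else None
        ),
        ms_level=int(d.get("ms_level", 2)),
        isolation_width=float(d.get("isolation_width", 1.2)),
        spectrum_id=str(d.get("id", fallback_id)),
    )


def read_spectra(path: str | Path) -> list[CentroidSpectrum]:
    """Read centroided MS/MS spectra from mzML or JSON peak lists."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise UnsupportedFormat(f"{path} is missing or empty")
    suffix = path.suffix.lower()
    if suffix == ".json":
        payload = json.loads(path.read_text())
        if "spectra" not in payload:
            raise UnsupportedFormat(f"{path} lacks the 'spectra' key")
        return [
            _spectrum_from_dict(d, f"scan_{i:05d}")
            for i, d in enumerate(payload["spectra"])
        ]
    if suffix == ".mzml":
        return _read_mzml(path)
    raise UnsupportedFormat(f"unsupported spectrum format {suffix!r} ({path})")


_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(node) -> np.ndarray:
    import base64
    import zlib

    accs = {cv.get("accession") for cv in node.iter(f"{_NS}cvParam")}
    raw = base64.b64decode((node.find(f"{_NS}binary").text or "").strip())
    if "MS:1000574" in accs:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[CentroidSpectrum]:
    """Minimal centroided-mzML reader (64/32-bit floats, zlib or no
    compression); MS1 scans are skipped, profile data rejected."""
    import xml.etree.ElementTree as ET

    out = []
    root = ET.parse(str(path)).getroot()
    for i, spec in enumerate(root.iter(f"{_NS}spectrum")):
        params = {cv.get("accession"): cv.get("value", "")
                  for cv in spec.findall(f"{_NS}cvParam")}
        if "MS:1000128" in params:  # profile spectrum
            raise ProfileModeData(
                f"{path} contains profile-mode spectra; convert with "
                "peak picking (e.g. msconvert --filter 'peakPicking')"
            )
        if int(params.get("MS:1000511", 1)) < 2:
            continue
        precursor = spec.find(f"{_NS}precursorList/{_NS}precursor")
        ion = precursor.find(f"{_NS}selectedIonList/{_NS}selectedIon")
        ion_params = {cv.get("accession"): cv.get("value", "")
                      for cv in ion.findall(f"{_NS}cvParam")}
        iso = precursor.find(f"{_NS}isolationWindow")
        width = 1.2
        if iso is not None:
            iso_params = {cv.get("accession"): cv.get("value", "")
                          for cv in iso.findall(f"{_NS}cvParam")}
            width = (float(iso_params.get("MS:1000828", 0.6))
                     + float(iso_params.get("MS:1000829", 0.6)))
        scan = spec.find(f"{_NS}scanList/{_NS}scan")
        rt = 0.0
        for cv in scan.findall(f"{_NS}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        arrays = {}
        for arr in spec.iter(f"{_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in arr.findall(f"{_NS}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary_array(arr)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary_array(arr)
        out.append(CentroidSpectrum(
            precursor_mz=float(ion_params["MS:1000744"]),
            rt=rt,
            polarity="negative" if "MS:1000129" in params else "positive",
            peaks=tuple(zip(arrays.get("mz", []), arrays.get("intensity", []))),
            precursor_intensity=float(ion_params.get("MS:1000042", 0.0)),
            ms_level=int(params.get("MS:1000511", 2)),
            isolation_width=width,
            spectrum_id=str(spec.get("id", f"scan_{i:05d}")),
        ))
    return out


def write_spectra_json(path: str | Path, spectra: Iterable[CentroidSpectrum]):
    payload = {"spectra": []}
    for s in spectra:
        d = {
            "precursor_mz": s.precursor_mz,
            "precursor_intensity": s.precursor_intensity,
            "rt": s.rt,
            "polarity": s.polarity,
            "peaks": [[m, i] for m, i in s.peaks],
            "ms_level": s.ms_level,
            "isolation_width": s.isolation_width,
            "id": s.spectrum_id,
        }
        if s.precursor_isotopes is not None:
            d["precursor_isotopes"] = list(s.precursor_isotopes)
        payload["spectra"].append(d)
    Path(path).write_text(json.dumps(payload))


def read_lipidome_csv(path: str | Path, sep: str = ",") -> LipidomeTable:
    """Read a feature x sample table whose first row (index ``group``)
    holds the per-sample group labels."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if "group" not in df.index:
        raise ValueError(f"{path} lacks a 'group' row with sample group labels")
    groups = df.loc["group"]
    values = df.drop(index="group").astype(float)
    return LipidomeTable(values, groups)


def write_lipidome_csv(path: str | Path, table: LipidomeTable, sep: str = ","):
    df = pd.concat([table.groups.to_frame("group").T, table.values])
    df.to_csv(path, sep=sep)


def write_inclusion_csv(path: str | Path, entries: Sequence[InclusionEntry]):
    pd.DataFrame([
        {"mz": e.mz, "z": 1, "polarity": e.polarity, "adduct": e.adduct,
         "species": e.species, "rt_start": e.rt_start, "rt_stop": e.rt_stop}
        for e in entries
    ]).to_csv(path, index=False)


def write_exclusion_csv(path: str | Path, entries: Sequence[ExclusionEntry]):
    pd.DataFrame([
        {"mz": e.mz, "mz_low": e.mz_range[0], "mz_high": e.mz_range[1],
         "rt": e.rt, "rt_start": e.rt_range[0], "rt_stop": e.rt_range[1]}
        for e in entries
    ]).to_csv(path, index=False)


def read_transitions_csv(path: str | Path) -> list[Transition]:
    df = pd.read_csv(path)
    required = {"name", "precursor_mz", "product_mz"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path} must contain columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(Transition(
            name=row["name"],
            precursor_mz=float(row["precursor_mz"]),
            product_mz=float(row["product_mz"]),
            precursor_adduct=row.get("precursor_adduct", "[M+NH4]+"),
            product_adduct=row.get("product_adduct", "[M+H]+"),
            expected_rt=(float(row["expected_rt_min"])
                         if "expected_rt_min" in df.columns and pd.notna(row["expected_rt_min"])
                         else None),
            collision_energy=(float(row["collision_energy"])
                              if "collision_energy" in df.columns and pd.notna(row["collision_energy"])
                              else None),
        ))
    return out


def read_kinetic_traces_csv(path: str | Path) -> dict[str, KineticTrace]:
    """Tidy trace CSV with columns time, signal, well[, channel]."""
    df = pd.read_csv(path)
    if not {"time", "signal", "well"}.issubset(df.columns):
        raise ValueError(f"{path} must contain columns time, signal, well")
    out = {}
    for well, sub in df.groupby("well"):
        sub = sub.sort_values("time")
        channel = sub["channel"].iloc[0] if "channel" in sub.columns else "oxidized BODIPY-C11"
        out[str(well)] = KineticTrace(
            sub["time"].to_numpy(float), sub["signal"].to_numpy(float), channel)
    return out


def write_identifications_tsv(path: str | Path, ids: Sequence[Identification]):
    pd.DataFrame([
        {"spectrum_id": i.spectrum_id, "species": i.species.name(),
         "adduct": i.adduct, "precursor_mz": i.precursor_mz, "rt": i.rt,
         "score": i.score, "isotope_score": i.isotope_score,
         "rank_score": i.rank_score, "accepted": i.accepted,
         "reasons": ";".join(i.reasons),
         "matched_fragments": ";".join(a.descriptor for a in i.matched)}
        for i in ids
    ]).to_csv(path, sep="\t", index=False)
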