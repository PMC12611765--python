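"""In-silico prediction of the sample-specific oxidized lipidome.

Selects a rational subset of the measured lipidome (per-class top-N by
intensity, optionally top-N positively phenotype-correlated) and
enumerates its predicted oxidation products under combinatorial
constraints on modification counts and added oxygens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .chem import (
    EMPTY_MODS,
    FattyAcyl,
    LipidSpecies,
    ModificationSet,
    parse_lipid_name,
)
from .tables import EmptyTable, LipidomeTable

__all__ = [
    "OxidationConstraints",
    "TargetSelectionConfig",
    "AlreadyOxidizedParent",
    "select_target_lipids",
    "enumerate_modification_sets",
    "enumerate_oxidized_species",
]


class AlreadyOxidizedParent(ValueError):
    """In-silico oxidation starts from an unmodified parent."""


@dataclass(frozen=True)
class OxidationConstraints:
    """Caps on the oxidation combinatorics.

    Defaults are the semi-targeted prediction settings: at most 2
    modification groups per lipid, at most 3 added oxygens, <=2 OH,
    <=1 keto, <=1 OOH, no epoxides.
    """

    max_mod_sites: int = 2
    max_total_O: int = 3
    max_OH: int = 2
    max_oxo: int = 1
    max_OOH: int = 1
    max_epoxy: int = 0

    def __post_init__(self):
        for v in (self.max_mod_sites, self.max_total_O, self.max_OH,
                  self.max_oxo, self.max_OOH, self.max_epoxy):
            if v < 0:
                raise ValueError("constraint caps must be >= 0")

    def allows(self, mods: ModificationSet) -> bool:
        return (
            mods.n_OH <= self.max_OH
            and mods.n_oxo <= self.max_oxo
            and mods.n_OOH <= self.max_OOH
            and mods.n_epoxy <= self.max_epoxy
            and mods.total_groups <= self.max_mod_sites
            and mods.added_oxygens <= self.max_total_O
        )


# default per-class top-N: 10 for the six phospholipid (sub)classes,
# 20 for the neutral-lipid classes
DEFAULT_TOP_N: Mapping[str, int] = {
    "PC": 10, "P-PC": 10, "O-PC": 10,
    "PE": 10, "P-PE": 10, "O-PE": 10,
    "TG": 20, "CE": 20,
}


@dataclass(frozen=True)
class TargetSelectionConfig:
    """Which measured lipids are carried into in-silico oxidation."""

    top_n_per_class: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_TOP_N))
    phenotype: Sequence[float] | None = None
    top_n_correlated: int = 10
    correlation_method: str = "pearson"

    def __post_init__(self):
        if any(n < 0 for n in self.top_n_per_class.values()) or self.top_n_correlated < 0:
            raise ValueError("top-N counts must be >= 0")
        if self.correlation_method != "pearson":
            raise ValueError("only Pearson correlation is supported")


def _class_key(species: LipidSpecies) -> str:
    prefix = {"O": "O-", "P": "P-", None: ""}[species.ether]
    return prefix + species.lipid_class


def select_target_lipids(
    table: LipidomeTable, config: TargetSelectionConfig | None = None
) -> list[LipidSpecies]:
    """Deduplicated union of per-class top-N-by-mean-intensity lipids and
    (when a phenotype vector is given) the top-N lipids most positively
    Pearson-correlated with it.

    Ties break by (mean intensity desc, name asc); the returned order is
    deterministic: per-class blocks in sorted class order, then the
    correlated additions.
    """
    config = config or TargetSelectionConfig()
    table.require_nonempty()
    raw = table.raw if table.raw is not None else table.values
    parsed = {name: parse_lipid_name(name) for name in raw.index}
    means = raw.mean(axis=1)

    chosen: list[str] = []
    seen: set[str] = set()
    for cls in sorted(config.top_n_per_class):
        n = config.top_n_per_class[cls]
        members = [name for name, sp in parsed.items() if _class_key(sp) == cls]
        members.sort(key=lambda name: (-means[name], name))
        for name in members[:n]:
            if name not in seen:
                seen.add(name)
                chosen.append(name)

    if config.phenotype is not None and config.top_n_correlated > 0:
        pheno = np.asarray(config.phenotype, dtype=float)
        if pheno.shape[0] != raw.shape[1]:
            raise ValueError("phenotype vector length must equal the sample count")
        x = raw.values
        xc = x - x.mean(axis=1, keepdims=True)
        pc = pheno - pheno.mean()
        denom = np.sqrt((xc ** 2).sum(axis=1) * (pc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xc @ pc) / denom, np.nan)
        corr = [
            (name, ri) for name, ri in zip(raw.index, r) if np.isfinite(ri) and ri > 0
        ]
        corr.sort(key=lambda t: (-t[1], t[0]))
        for name, _ in corr[: config.top_n_correlated]:
            if name not in seen:
                seen.add(name)
                chosen.append(name)

    return [parsed[name] for name in chosen]


def enumerate_modification_sets(
    constraints: OxidationConstraints | None = None,
) -> list[ModificationSet]:
    """All distinct non-empty modification sets allowed by the caps,
    in canonical order (total groups, added oxygens, counts)."""
    c = constraints or OxidationConstraints()
    out = []
    for n_oh in range(c.max_OH + 1):
        for n_oxo in range(c.max_oxo + 1):
            for n_ooh in range(c.max_OOH + 1):
                for n_ep in range(c.max_epoxy + 1):
                    mods = ModificationSet(n_oh, n_oxo, n_ooh, n_ep)
                    if mods and c.allows(mods):
                        out.append(mods)
    out.sort(key=lambda m: (m.total_groups, m.added_oxygens,
                            m.n_OH, m.n_oxo, m.n_OOH, m.n_epoxy))
    return out


def _most_unsaturated_index(chains: Sequence[FattyAcyl]) -> int:
    best, best_db = 0, -1
    for i, c in enumerate(chains):
        if c.double_bonds > best_db:
            best, best_db = i, c.double_bonds
    return best


def enumerate_oxidized_species(
    parent: LipidSpecies, constraints: OxidationConstraints | None = None
) -> list[LipidSpecies]:
    """Predicted oxidation products of one unmodified parent.

    Eligibility requires at least one double bond among the acyl chains;
    fully saturated parents yield nothing.  Chain-resolved parents carry
    the modification set on their most unsaturated chain (sum-composition
    semantics otherwise), species-level parents at the species level.
    """
    if parent.is_oxidized:
        raise AlreadyOxidizedParent(f"parent {parent} already carries modifications")
    if parent.named:
        raise AlreadyOxidizedParent(f"named compound {parent} is not an oxidation substrate")
    if parent.total_double_bonds < 1:
        return []
    out = []
    for mods in enumerate_modification_sets(constraints):
        if parent.chains is not None:
            idx = _most_unsaturated_index(parent.chains)
            chains = tuple(
                replace(c, modifications=mods) if i == idx else c
                for i, c in enumerate(parent.chains)
            )
            out.append(replace(parent, chains=chains))
        else:
            out.append(replace(parent, modifications=mods))
    return out
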