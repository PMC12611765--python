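"""The feature x sample intensity container carried through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LipidomeTable", "EmptyTable"]


class EmptyTable(ValueError):
    """Operation requires a non-empty lipidome table."""


@dataclass
class LipidomeTable:
    """Lipid shorthand features x samples with group labels.

    ``values`` holds the current (possibly transformed) matrix; ``raw``
    always keeps the original non-negative intensities so fold changes
    can be computed on the raw scale after transformation.  ``state``
    tracks the processing stage and may only advance
    raw -> log10 -> autoscaled.
    """

    values: pd.DataFrame
    groups: pd.Series
    state: str = "raw"
    raw: pd.DataFrame | None = None
    flags: pd.DataFrame | None = field(default=None, repr=False)

    _STATES = ("raw", "log10", "autoscaled")

    def __post_init__(self):
        if self.state not in self._STATES:
            raise ValueError(f"unknown state {self.state!r}")
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups)
        if not self.groups.index.equals(pd.Index(self.values.columns)):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if self.state == "raw":
            if (self.values.values < 0).any():
                raise ValueError("raw intensities must be non-negative")
            if self.raw is None:
                self.raw = self.values.copy()
        elif self.raw is None:
            raise ValueError("transformed tables must carry the raw matrix")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return len(self.values.index)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def advanced(self, values: pd.DataFrame, state: str,
                 flags: pd.DataFrame | None = None) -> "LipidomeTable":
        """Return a copy at the next processing state."""
        if self._STATES.index(state) != self._STATES.index(self.state) + 1:
            raise ValueError(f"illegal state transition {self.state} -> {state}")
        return LipidomeTable(values=values, groups=self.groups, state=state,
                             raw=self.raw, flags=flags if flags is not None else self.flags)

    def require_nonempty(self):
        if self.values.empty:
            raise EmptyTable("lipidome table has no features or samples")
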