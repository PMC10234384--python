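"""Genotype matrix container shared by all pipeline stages.

Calls are single characters: ``A``/``B`` parental homozygotes, ``H``
heterozygote, ``-`` missing. Markers are kept sorted by (chromosome,
position); positions are 0-based bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_SYMBOLS = frozenset("ABH-")
MISSING = "-"


@dataclass
class GenotypeMatrix:
    """Markers x lines call table with marker coordinates.

    Parameters
    ----------
    markers : pandas.DataFrame
        Columns ``id``, ``chromosome``, ``position`` (int bp), one row per
        marker, in (chromosome, position) order.
    lines : list of str
        Line identifiers, one per call column.
    calls : numpy.ndarray
        Shape ``(n_markers, n_lines)``, dtype ``<U1``, values in
        ``{A, B, H, -}``.
    population_label : str
        Free-text population tag carried into downstream outputs.
    """

    markers: pd.DataFrame
    lines: list[str]
    calls: np.ndarray
    population_label: str = ""
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype="<U1")
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        required = {"id", "chromosome", "position"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"marker table needs columns {sorted(required)}")
        if self.calls.shape != (len(self.markers), len(self.lines)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.markers)}, {len(self.lines)})"
            )
        if self.markers["id"].duplicated().any():
            dup = self.markers.loc[self.markers["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup!r}")
        bad = ~np.isin(self.calls, list(CALL_SYMBOLS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"unknown call symbol {self.calls[i, j]!r} at marker "
                f"{self.markers['id'].iloc[i]!r}, line {self.lines[j]!r}"
            )
        key = self.markers[["chromosome", "position"]]
        if not key.equals(key.sort_values(["chromosome", "position"], ignore_index=True)):
            raise ValueError("markers must be sorted by (chromosome, position)")
        self._validated = True

    # -- convenience ------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chromosome"]))

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            markers=self.markers.iloc[keep].reset_index(drop=True),
            lines=list(self.lines),
            calls=self.calls[keep],
            population_label=self.population_label,
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)
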