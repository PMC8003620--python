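"""The swallowability index, rank bands and the swallowability matrix.

Five critical factors measured on a film-coated tablet are combined into
a single dimensionless index::

    SI = 1000 · GL / (CA · Wa · 10F · CoF)

where GL is the axial gel-layer thickness change (%), CA the apparent
contact angle (degrees), Wa the work of adhesion (J/mm²), F the force
required to initiate movement (N, entering as 10·F) and CoF the
coefficient of sliding friction.  A large hydration response (GL) helps
gliding; large wetting angles, adhesion energies, detachment forces and
friction hinder it.  Uncoated tablets show no measurable swelling
(GL = 0) and take SI = 0 by convention.

Indices map onto five ordered rank bands::

    SI = 0        Poor
    0 < SI < 1    Pass
    1 ≤ SI < 2    Good
    2 ≤ SI < 4    Very Good
    SI ≥ 4        Excellent

(half-open on the left so every non-negative SI has exactly one rank).
A *swallowability matrix* collects SI values over a grid of in-vitro
oral transit times (4-20 s) for a panel of formulations, with a
colour-coded rank per cell.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SI_TIMES_S",
    "Rank",
    "SwallowabilityRecord",
    "SwallowabilityMatrix",
    "swallowability_index",
    "classify_si",
    "build_matrix",
    "rank_formulations",
]

#: Default in-vitro oral transit time grid for the matrix, seconds.
SI_TIMES_S = (4, 8, 12, 16, 20)


class Rank(enum.IntEnum):
    """Ordered swallowability rank bands (ascending quality)."""

    POOR = 0
    PASS = 1
    GOOD = 2
    VERY_GOOD = 3
    EXCELLENT = 4

    @property
    def label(self) -> str:
        return {
            Rank.POOR: "Poor",
            Rank.PASS: "Pass",
            Rank.GOOD: "Good",
            Rank.VERY_GOOD: "Very Good",
            Rank.EXCELLENT: "Excellent",
        }[self]

    @property
    def color(self) -> str:
        return {
            Rank.POOR: "red",
            Rank.PASS: "orange",
            Rank.GOOD: "yellow",
            Rank.VERY_GOOD: "limegreen",
            Rank.EXCELLENT: "darkgreen",
        }[self]


def swallowability_index(
    GL: float, CA: float, Wa: float, F: float, CoF: float
) -> float:
    """Swallowability index ``SI = 1000·GL / (CA · Wa · 10F · CoF)``.

    ``GL = 0`` (no measurable swelling, e.g. an uncoated tablet) returns
    exactly 0 without touching the denominator.  Negative GL or a
    non-positive denominator factor is rejected.
    """
    if GL < 0:
        raise ValueError("GL must be >= 0")
    if GL == 0:
        return 0.0
    for name, value in (("CA", CA), ("Wa", Wa), ("F", F), ("CoF", CoF)):
        if value <= 0:
            raise ValueError(f"{name} must be > 0 when GL > 0 (got {value!r})")
    return 1000.0 * GL / (CA * Wa * (10.0 * F) * CoF)


def classify_si(si: float) -> Rank:
    """Map a swallowability index onto its rank band."""
    if si < 0:
        raise ValueError("SI must be >= 0")
    if si == 0:
        return Rank.POOR
    if si < 1:
        return Rank.PASS
    if si < 2:
        return Rank.GOOD
    if si < 4:
        return Rank.VERY_GOOD
    return Rank.EXCELLENT


@dataclass
class SwallowabilityRecord:
    """The five factors, SI and rank for one formulation at one time.

    ``si`` and ``rank`` are computed on construction when not supplied.
    Factor values may be ``None`` when a stage failed; the record then
    carries ``si=None`` unless ``GL == 0`` forces ``si = 0``.
    """

    formulation_id: str
    time_s: float
    GL: float | None = None
    CA: float | None = None
    Wa: float | None = None
    F: float | None = None
    CoF: float | None = None
    si: float | None = field(default=None)
    rank: Rank | None = field(default=None)

    def __post_init__(self) -> None:
        if self.si is None:
            if self.GL == 0:
                self.si = 0.0
            elif None not in (self.GL, self.CA, self.Wa, self.F, self.CoF):
                self.si = swallowability_index(self.GL, self.CA, self.Wa, self.F, self.CoF)
        if self.rank is None and self.si is not None:
            self.rank = classify_si(self.si)


@dataclass
class SwallowabilityMatrix:
    """Formulations × transit-times table of SI values with ranks.

    ``values`` holds the SI per cell (NaN = missing), ``ranks`` the
    corresponding :class:`Rank` (or ``None`` where missing).
    """

    values: pd.DataFrame
    ranks: pd.DataFrame

    @property
    def formulations(self) -> list[str]:
        return list(self.values.index)

    @property
    def times(self) -> list[float]:
        return list(self.values.columns)

    def missing_cells(self) -> list[tuple[str, float]]:
        mask = self.values.isna()
        return [(r, c) for r in self.values.index for c in self.values.columns if mask.at[r, c]]

    def to_csv(self) -> str:
        """Serialise SI values to CSV text; float repr round-trips exactly."""
        buf = io.StringIO()
        self.values.to_csv(buf, index_label="formulation_id")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "SwallowabilityMatrix":
        df = pd.read_csv(io.StringIO(text), index_col="formulation_id")
        df.columns = [float(c) for c in df.columns]
        ranks = df.map(lambda v: classify_si(v) if pd.notna(v) else None)
        return cls(values=df, ranks=ranks)

    def to_html(self) -> str:
        """Minimal colour-coded HTML rendering of the matrix."""
        rows = ["<table border='1'>"]
        header = "".join(f"<th>{c:g} s</th>" for c in self.values.columns)
        rows.append(f"<tr><th>formulation</th>{header}</tr>")
        for name in self.values.index:
            cells = []
            for c in self.values.columns:
                v = self.values.at[name, c]
                r = self.ranks.at[name, c]
                if pd.isna(v) or r is None:
                    cells.append("<td>-</td>")
                else:
                    cells.append(
                        f"<td style='background:{r.color}' title='{r.label}'>{v:.2f}</td>"
                    )
            rows.append(f"<tr><td>{name}</td>{''.join(cells)}</tr>")
        rows.append("</table>")
        return "\n".join(rows)


def build_matrix(records: list[SwallowabilityRecord]) -> SwallowabilityMatrix:
    """Assemble records into a swallowability matrix.

    Each (formulation, time) pair may appear at most once; duplicates are
    rejected.  Cells without a record (or with ``si=None``) are NaN and
    reported by :meth:`SwallowabilityMatrix.missing_cells`.
    """
    if not records:
        empty = pd.DataFrame(dtype=float)
        return SwallowabilityMatrix(values=empty, ranks=empty.copy())
    seen: set[tuple[str, float]] = set()
    for rec in records:
        key = (rec.formulation_id, float(rec.time_s))
        if key in seen:
            raise ValueError(f"duplicate cell for {key}")
        seen.add(key)
    formulations = list(dict.fromkeys(r.formulation_id for r in records))
    times = sorted({float(r.time_s) for r in records})
    values = pd.DataFrame(np.nan, index=formulations, columns=times, dtype=float)
    ranks = pd.DataFrame(
        np.full((len(formulations), len(times)), None, dtype=object),
        index=formulations,
        columns=times,
    )
    for rec in records:
        if rec.si is not None:
            values.at[rec.formulation_id, float(rec.time_s)] = rec.si
            ranks.at[rec.formulation_id, float(rec.time_s)] = rec.rank
    return SwallowabilityMatrix(values=values, ranks=ranks)


def rank_formulations(
    matrix: SwallowabilityMatrix, time_s: float | None = None
) -> list[str]:
    """Order formulations by ascending SI; ties break alphabetically.

    ``time_s`` selects one transit-time column; ``None`` orders by the
    row-mean SI across all columns (the ordering used for an overall
    performance ranking).  Missing cells sort first (treated as 0).
    """
    if matrix.values.empty:
        return []
    if time_s is None:
        key = matrix.values.mean(axis=1, skipna=True)
    else:
        time_s = float(time_s)
        if time_s not in matrix.values.columns:
            raise KeyError(f"no column for transit time {time_s} s")
        key = matrix.values[time_s]
    key = key.fillna(0.0)
    order = sorted(key.index, key=lambda name: (key[name], name))
    return list(order)
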