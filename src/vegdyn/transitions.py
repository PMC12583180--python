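"""Grade-transition accounting between classification epochs.

A :class:`TransitionMatrix` holds the class-by-class area matrix (km^2)
between a start and an end epoch: entry ``s_ij`` is the area that moved from
class i to class j.  From it derive net change per class (column total minus
row total), inflow/outflow percentage shares, the total changed area
(off-diagonal sum), and long-format flow tables for Sankey rendering.
Matrices can be built from co-registered classified rasters or directly from
a published area table, so printed tables can be re-analysed without
rasters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ClassifiedGrid

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "net_change",
    "flow_shares",
    "changed_area",
    "grade_area_summary",
    "export_sankey",
]


@dataclass
class TransitionMatrix:
    area: np.ndarray          # K x K, km^2; rows = start class, cols = end class
    labels: list

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        k = len(self.labels)
        if self.area.shape != (k, k):
            raise ValueError(f"area matrix shape {self.area.shape} != ({k},{k})")
        if (self.area < 0).any():
            raise ValueError("transition areas must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.area.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.area.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.area.sum())

    def index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.area, index=self.labels, columns=self.labels)
        df["Total"] = self.row_totals
        df.loc["Total"] = list(self.col_totals) + [self.grand_total]
        return df

    @classmethod
    def from_table(cls, table, labels=None) -> "TransitionMatrix":
        """Build from a printed area table (nested list / array / DataFrame)."""
        if isinstance(table, pd.DataFrame):
            labels = list(table.index) if labels is None else list(labels)
            return cls(table.to_numpy(dtype=float), labels)
        arr = np.asarray(table, dtype=float)
        if labels is None:
            labels = [f"class {i + 1}" for i in range(arr.shape[0])]
        return cls(arr, list(labels))


def transition_matrix(start: ClassifiedGrid, end: ClassifiedGrid,
                      cell_area_km2: float) -> TransitionMatrix:
    """Cross-tabulate two co-registered classified grids into an area matrix.

    Pixels masked in either epoch are excluded.  Both grids must share the
    class dictionary (250 m cells -> ``cell_area_km2 = 0.0625``).
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    if not start.grid.same_geometry(end.grid):
        raise ValueError("start and end grids are not co-registered")
    if start.classes != end.classes:
        raise ValueError("start and end class dictionaries differ")
    codes = start.codes
    valid = ~(start.grid.nodata_mask | end.grid.nodata_mask)
    s = start.grid.values[valid]
    e = end.grid.values[valid]
    code_to_idx = {c: i for i, c in enumerate(codes)}
    k = len(codes)
    si = np.vectorize(code_to_idx.get)(s) if s.size else np.array([], dtype=int)
    ei = np.vectorize(code_to_idx.get)(e) if e.size else np.array([], dtype=int)
    counts = np.bincount(si * k + ei, minlength=k * k).reshape(k, k)
    return TransitionMatrix(counts * cell_area_km2, [start.classes[c] for c in codes])


def net_change(tm: TransitionMatrix, class_label) -> float:
    """Signed area change of a class: end-epoch total minus start-epoch total."""
    i = tm.index(class_label)
    return float(tm.col_totals[i] - tm.row_totals[i])


def flow_shares(tm: TransitionMatrix, class_label, direction: str) -> dict:
    """Percentage composition of a class's off-diagonal outflow or inflow.

    ``outflow``: where the class's lost area went (row entries, diagonal
    excluded).  ``inflow``: where its gained area came from (column entries,
    diagonal excluded).  Shares sum to 100.
    """
    if direction not in ("outflow", "inflow"):
        raise ValueError("direction must be 'outflow' or 'inflow'")
    i = tm.index(class_label)
    vec = tm.area[i, :].copy() if direction == "outflow" else tm.area[:, i].copy()
    vec[i] = 0.0
    total = vec.sum()
    if total <= 0:
        warnings.warn(f"class {class_label!r} has zero off-diagonal {direction}",
                      stacklevel=2)
        return {}
    return {lab: float(100.0 * v / total)
            for lab, v in zip(tm.labels, vec) if lab != class_label}


def changed_area(tm: TransitionMatrix) -> float:
    """Total inter-class converted area: sum of off-diagonal entries (km^2)."""
    return float(tm.area.sum() - np.trace(tm.area))


def grade_area_summary(classified, cell_area_km2: float = None) -> pd.DataFrame:
    """Per-class area and percentage table.

    Accepts a ClassifiedGrid plus ``cell_area_km2``, or a mapping
    ``{label: area_km2}`` taken directly from a printed table.
    """
    if isinstance(classified, ClassifiedGrid):
        if cell_area_km2 is None or cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive for raster input")
        areas = classified.area_km2(cell_area_km2)
        rows = [(classified.classes[c], areas[c]) for c in classified.codes]
    else:
        rows = [(lab, float(a)) for lab, a in classified.items()]
    total = sum(a for _, a in rows)
    if total <= 0:
        raise ValueError("total area is zero")
    return pd.DataFrame(
        {"class": [lab for lab, _ in rows],
         "area_km2": [a for _, a in rows],
         "percentage": [100.0 * a / total for _, a in rows]})


def export_sankey(tms, epoch_names=None) -> pd.DataFrame:
    """Long-format (epoch, source, target, area) flow table for Sankey plots."""
    tms = list(tms)
    if not tms:
        raise ValueError("need at least one transition matrix")
    labels = tms[0].labels
    for tm in tms[1:]:
        if tm.labels != labels:
            raise ValueError("consecutive transition matrices must share labels")
    if epoch_names is None:
        epoch_names = [f"epoch {i + 1}" for i in range(len(tms))]
    records = []
    for name, tm in zip(epoch_names, tms):
        for i, src in enumerate(labels):
            for j, dst in enumerate(labels):
                records.append((name, src, dst, float(tm.area[i, j])))
    return pd.DataFrame(records, columns=["epoch", "source", "target", "area_km2"])
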