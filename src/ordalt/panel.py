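"""Ordinal panel containers: wide-format category data, margins, crosstabs.

An :class:`OrdinalPanel` holds one row per subject and one integer column per
(variable, occasion) cell, categories coded 0..C-1.  Missing data is handled by
listwise deletion only, so that the Stage-1 (threshold/polychoric) and Stage-2
(structural) samples are identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinalPanel",
    "MarginTable",
    "ContingencyTable",
    "load_panel",
    "margins",
    "crosstab",
]


class PanelFormatError(ValueError):
    """Raised for unmappable codes or out-of-range categories."""


class PanelSpecError(ValueError):
    """Raised for structurally invalid panels (e.g. fewer than two occasions)."""


@dataclass(frozen=True)
class OrdinalPanel:
    """Subjects x (variables * occasions) matrix of ordinal categories.

    ``data`` has shape (n, V*T) with columns ordered variable-major: all T
    occasions of variable 0, then variable 1, etc.  ``C`` gives the number of
    categories per variable; every cell of variable v lies in {0, .., C[v]-1}.
    """

    data: np.ndarray
    T: int
    C: tuple[int, ...]
    var_names: tuple[str, ...] = field(default=())
    n_dropped: int = 0

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise PanelSpecError("panel data must be 2-D (subjects x columns)")
        if self.T < 2:
            raise PanelSpecError("at least two occasions are required")
        V = len(self.C)
        if data.shape[1] != V * self.T:
            raise PanelSpecError(
                f"expected {V * self.T} columns (V={V}, T={self.T}), got {data.shape[1]}"
            )
        if data.shape[0] < 1:
            raise PanelSpecError("panel must contain at least one subject")
        if not np.issubdtype(data.dtype, np.integer):
            if np.any(data != np.floor(data)) or not np.all(np.isfinite(data)):
                raise PanelFormatError("non-integer category codes present")
            data = data.astype(np.int64)
        for v, c in enumerate(self.C):
            if c < 2:
                raise PanelSpecError(f"variable {v} needs at least 2 categories")
            block = data[:, v * self.T : (v + 1) * self.T]
            if block.min() < 0 or block.max() > c - 1:
                raise PanelFormatError(
                    f"variable {v}: codes outside 0..{c - 1} "
                    f"(observed range {block.min()}..{block.max()})"
                )
        object.__setattr__(self, "data", data)
        names = self.var_names or tuple(f"y{v}" for v in range(V))
        object.__setattr__(self, "var_names", tuple(names))

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def V(self) -> int:
        return len(self.C)

    def column(self, v: int, t: int) -> np.ndarray:
        """Categories of variable v at occasion t (0-based)."""
        return self.data[:, v * self.T + t]

    def col_index(self, v: int, t: int) -> int:
        return v * self.T + t

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.var_names[v]}_t{t + 1}" for v in range(self.V) for t in range(self.T)]
        return pd.DataFrame(self.data, columns=cols)


@dataclass(frozen=True)
class MarginTable:
    """Per-occasion category counts n_{r,t} for one variable."""

    counts: np.ndarray  # (T, C)
    n: int

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def degenerate_occasions(self) -> np.ndarray:
        """Occasions where some category is unobserved (flagged, not collapsed)."""
        return np.flatnonzero(np.any(self.counts == 0, axis=1))

    def to_frame(self) -> pd.DataFrame:
        T, C = self.counts.shape
        return pd.DataFrame(
            self.counts,
            index=[f"t{t + 1}" for t in range(T)],
            columns=[f"cat{c}" for c in range(C)],
        )


@dataclass(frozen=True)
class ContingencyTable:
    """C_i x C_j count matrix for a pair of panel columns."""

    cells: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        Ci, Cj = self.cells.shape
        return pd.DataFrame(
            self.cells,
            index=[f"row{c}" for c in range(Ci)],
            columns=[f"col{c}" for c in range(Cj)],
        )


def margins(panel: OrdinalPanel, v: int = 0) -> MarginTable:
    """Category counts per occasion for variable ``v``; proportions sum to 1."""
    C = panel.C[v]
    counts = np.zeros((panel.T, C), dtype=np.int64)
    for t in range(panel.T):
        counts[t] = np.bincount(panel.column(v, t), minlength=C)
    table = MarginTable(counts=counts, n=panel.n)
    if table.degenerate_occasions.size:
        logger.warning(
            "variable %s: unobserved categories at occasions %s; thresholds for "
            "empty extreme categories will be +-inf",
            panel.var_names[v],
            (table.degenerate_occasions + 1).tolist(),
        )
    return table


def crosstab(panel: OrdinalPanel, i: int, j: int) -> ContingencyTable:
    """Contingency table of panel columns ``i`` and ``j`` (flat indices, i != j)."""
    if i == j:
        raise ValueError("crosstab requires two distinct columns")
    vi, vj = i // panel.T, j // panel.T
    Ci, Cj = panel.C[vi], panel.C[vj]
    idx = panel.data[:, i] * Cj + panel.data[:, j]
    cells = np.bincount(idx, minlength=Ci * Cj).reshape(Ci, Cj)
    return ContingencyTable(cells=cells, n=panel.n)


def load_panel(
    path: str | Path,
    *,
    T: int,
    C: int | Sequence[int],
    var_names: Sequence[str] | None = None,
    columns: Mapping[str, Sequence[str]] | None = None,
    label_map: Mapping[object, int] | None = None,
    sep: str = ",",
) -> OrdinalPanel:
    """Read a wide delimited file into a validated :class:`OrdinalPanel`.

    Parameters
    ----------
    T, C
        Occasions per variable, and categories per variable (scalar for a single
        variable or one entry per variable).
    columns
        Optional mapping variable name -> list of its T column names; defaults
        to ``{name}_t1 .. {name}_tT`` or, for a single unnamed variable, the
        first T columns of the file.
    label_map
        Optional label -> 0-based code map applied before validation.

    Rows with any missing cell are listwise-deleted; the count is logged and
    recorded on the panel.
    """
    df = pd.read_csv(path, sep=sep)
    C_list = [C] * 1 if np.isscalar(C) else list(C)
    if var_names is None:
        var_names = [f"y{v}" for v in range(len(C_list))]
    if np.isscalar(C) and columns is None and len(var_names) == 1 and not any(
        f"{var_names[0]}_t1" in df.columns for _ in (0,)
    ):
        use_cols = list(df.columns[:T])
    else:
        if columns is None:
            columns = {name: [f"{name}_t{t + 1}" for t in range(T)] for name in var_names}
        use_cols = [c for name in var_names for c in columns[name]]
        missing = [c for c in use_cols if c not in df.columns]
        if missing:
            raise PanelFormatError(f"columns not found in file: {missing}")
    raw = df[use_cols]
    if label_map is not None:
        raw = raw.apply(lambda s: s.map(lambda x: label_map.get(x, x)))
    arr = raw.to_numpy()
    # Coerce to float first so that NaN-missing survives; unmappable strings fail.
    try:
        arr = arr.astype(float)
    except (TypeError, ValueError) as exc:
        raise PanelFormatError(f"non-numeric, unmappable codes in panel: {exc}") from exc
    keep = ~np.any(np.isnan(arr), axis=1)
    n_before, n_after = arr.shape[0], int(keep.sum())
    if n_after < n_before:
        logger.info("listwise deletion: n %d -> %d", n_before, n_after)
    if n_after == 0:
        raise PanelSpecError("no complete cases after listwise deletion")
    return OrdinalPanel(
        data=arr[keep],
        T=T,
        C=tuple(int(c) for c in C_list),
        var_names=tuple(var_names),
        n_dropped=n_before - n_after,
    )


def panel_from_array(
    data: np.ndarray, T: int, C: int | Sequence[int], var_names: Sequence[str] | None = None
) -> OrdinalPanel:
    """Build a panel from an in-memory integer matrix (listwise-complete)."""
    C_list = [int(C)] if np.isscalar(C) else [int(c) for c in C]
    return OrdinalPanel(
        data=np.asarray(data), T=T, C=tuple(C_list), var_names=tuple(var_names or ())
    )
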