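"""Electrode grid geometry for 8x8 MEA layouts with absent corners."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Rectangular MEA electrode grid.

    The standard layout (``GridGeometry.standard_60()``) is an 8x8 grid with
    200 um pitch whose four corner positions carry no electrode, giving 60
    active electrodes -- the commercial 60MEA200 arrangement.

    Attributes
    ----------
    n_rows, n_cols
        Grid dimensions.
    pitch_um
        Center-to-center electrode spacing in micrometres.
    missing
        Grid positions (row, col) without an electrode.
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch_um: float = 200.0
    missing: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        for r, c in self.missing:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"missing position {(r, c)} outside grid")

    @classmethod
    def standard_60(cls) -> "GridGeometry":
        """8x8, 200 um pitch, four corners absent (60 electrodes)."""
        corners = frozenset({(0, 0), (0, 7), (7, 0), (7, 7)})
        return cls(n_rows=8, n_cols=8, pitch_um=200.0, missing=corners)

    @property
    def positions(self) -> list[tuple[int, int]]:
        """Active (row, col) positions in row-major order."""
        return [
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if (r, c) not in self.missing
        ]

    @property
    def electrode_ids(self) -> list[str]:
        """Labels '<col+1><row+1>' following the vendor naming (e.g. '12')."""
        return [f"{c + 1}{r + 1}" for r, c in self.positions]

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)

    def coordinates_um(self) -> np.ndarray:
        """(n_electrodes, 2) array of (x, y) positions in micrometres."""
        pos = np.asarray(self.positions, dtype=float)
        # x along columns, y along rows
        return np.column_stack([pos[:, 1], pos[:, 0]]) * self.pitch_um

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """Index pairs of 4-neighbouring electrodes (x or y direction).

        Indices refer to the row-major ordering of :attr:`positions`.
        """
        index = {p: i for i, p in enumerate(self.positions)}
        pairs: list[tuple[int, int]] = []
        for (r, c), i in index.items():
            for dr, dc in ((0, 1), (1, 0)):
                j = index.get((r + dr, c + dc))
                if j is not None:
                    pairs.append((i, j))
        return pairs
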