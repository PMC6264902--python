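"""Binary retina pattern container.

A pattern is an n_rows x n_cols matrix of ommatidial colour states
``a_ij in {0, 1}`` (0 = red/pale, 1 = green/yellow).  Column 0 is the
posterior-most column and generation proceeds with increasing column index,
following the morphogenetic furrow; display-time flipping so that anterior
appears on the left is handled by the renderer only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RetinaPattern"]


@dataclass(frozen=True, eq=False)
class RetinaPattern:
    cells: np.ndarray
    #: column 0 is posterior-most; generation order follows increasing j
    furrow_axis: str = field(default="posterior_to_anterior", compare=False)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim != 2:
            raise ValueError(f"pattern must be 2-D, got shape {cells.shape}")
        if cells.shape[0] < 1 or cells.shape[1] < 1:
            raise ValueError(f"pattern dimensions must be >= 1, got {cells.shape}")
        if not np.isin(cells, (0, 1)).all():
            raise ValueError("pattern cells must all be 0 or 1")
        object.__setattr__(self, "cells", cells.astype(np.uint8))

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def green_fraction(self) -> float:
        """Fraction of green (1) ommatidia."""
        return float(self.cells.mean())

    def column(self, j: int) -> np.ndarray:
        return self.cells[:, j]

    def flipped_colors(self) -> "RetinaPattern":
        """Pattern with the two colours exchanged (0 <-> 1)."""
        return RetinaPattern(1 - self.cells)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RetinaPattern):
            return NotImplemented
        return self.cells.shape == other.cells.shape and bool(
            (self.cells == other.cells).all()
        )
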