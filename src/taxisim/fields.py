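"""Static 2-D ligand concentration fields on the simulated plate.

Two built-in shapes (concentrations in µM, positions in mm):

* mountain: a ridge along the y axis, [L] = L0·exp(−((x−x0)/r)²)
* peak: a radially symmetric summit, [L] = L0·exp(−((x−x0)²+(y−y0)²)/r²)

The plate is an unbounded plane and the field is constant in time; the
Gaussian decay makes concentrations negligible far from the crest, so no
boundary handling is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ConcentrationField", "field_concentration"]


@dataclass(frozen=True)
class ConcentrationField:
    shape: str = "mountain"   # "mountain" | "peak" | "custom"
    L0: float = 2.0           # µM at the crest
    r: float = 2.0            # mm length scale
    offset: tuple = (0.0, 0.0)  # crest position (mm)
    func: Callable | None = None  # custom: (x, y) -> µM

    def __post_init__(self):
        if self.shape not in ("mountain", "peak", "custom"):
            raise ValueError(f"unknown field shape {self.shape!r}")
        if self.shape == "custom" and self.func is None:
            raise ValueError("custom field requires func")
        if self.L0 < 0 or self.r <= 0:
            raise ValueError("need L0 >= 0 and r > 0")

    def concentration(self, x, y):
        return field_concentration(self, (x, y))


def field_concentration(field: ConcentrationField, position):
    """Ligand concentration (µM) at ``position`` = (x, y) in mm.

    Vectorized over arrays of coordinates.
    """
    x = np.asarray(position[0], dtype=float) - field.offset[0]
    y = np.asarray(position[1], dtype=float) - field.offset[1]
    if field.shape == "mountain":
        L = field.L0 * np.exp(-((x / field.r) ** 2))
    elif field.shape == "peak":
        L = field.L0 * np.exp(-(x**2 + y**2) / field.r**2)
    else:
        L = np.asarray(field.func(x, y), dtype=float)
    return L if np.ndim(L) else float(L)
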