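"""Voxel grid geometry shared by the mask and volume builders.

Coordinates are in cm.  x and y are centered on the grid (x, y in
[-Lx/2, Lx/2] etc.); z runs downward from the tissue surface at z = 0.
x is transverse to the artery, y runs along it (and along the
source-detector axis), z is depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Voxel counts and physical extents of the simulation domain."""

    nx: int = 200
    ny: int = 100
    nz: int = 100
    lx_cm: float = 1.4
    ly_cm: float = 1.4
    lz_cm: float = 0.8

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be positive")
        if min(self.lx_cm, self.ly_cm, self.lz_cm) <= 0:
            raise ValueError("physical extents must be positive")

    @property
    def dx(self) -> float:
        return self.lx_cm / self.nx

    @property
    def dy(self) -> float:
        return self.ly_cm / self.ny

    @property
    def dz(self) -> float:
        return self.lz_cm / self.nz

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx - self.lx_cm / 2.0

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy - self.ly_cm / 2.0

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    @classmethod
    def coarse(cls) -> "GridSpec":
        """100 x 50 x 50 grid over the same domain (reduced-budget runs)."""
        return cls(nx=100, ny=50, nz=50)
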