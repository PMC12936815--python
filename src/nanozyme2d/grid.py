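"""Tensor-product grids for the diffusion layer.

The vertical coordinate is vertex-centred and geometrically stretched
toward the reactive surface at y = 0, where concentration gradients are
steepest; the lateral coordinate is uniform.  Control volumes are the dual
cells around each node (half cells at boundaries), which makes the
finite-volume discretisation conservative: summing the discrete balances
telescopes interior face fluxes and equates the influx through the top
boundary with the integrated surface consumption exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid1D", "Grid2D", "stretched_nodes", "make_grid"]


def stretched_nodes(H: float, n_cells: int, ratio: float = 1.05) -> np.ndarray:
    """Node coordinates 0..H with cell widths growing geometrically.

    ``ratio`` is the growth factor between adjacent cells; ratio = 1 gives a
    uniform grid.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if abs(ratio - 1.0) < 1e-12:
        return np.linspace(0.0, H, n_cells + 1)
    widths = ratio ** np.arange(n_cells)
    widths *= H / widths.sum()
    y = np.concatenate(([0.0], np.cumsum(widths)))
    y[-1] = H
    return y


@dataclass(frozen=True)
class Grid1D:
    """Vertex-centred vertical grid over [0, H]."""

    y: np.ndarray          # nodes, ascending, y[0]=0, y[-1]=H

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def H(self) -> float:
        return float(self.y[-1])

    @property
    def dy(self) -> np.ndarray:
        """Cell widths between consecutive nodes."""
        return np.diff(self.y)

    @property
    def vol(self) -> np.ndarray:
        """Dual-cell widths around each node (half cells at ends)."""
        dy = self.dy
        v = np.empty(self.n)
        v[0] = 0.5 * dy[0]
        v[-1] = 0.5 * dy[-1]
        v[1:-1] = 0.5 * (dy[:-1] + dy[1:])
        return v

    def cells_within(self, depth: float) -> int:
        """Number of cells entirely inside y < depth."""
        return int(np.searchsorted(self.y, depth, side="right")) - 1


@dataclass(frozen=True)
class Grid2D:
    """Tensor grid: uniform x over [0, L], stretched y over [0, H]."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        for name, c in (("x", self.x), ("y", self.y)):
            if np.any(np.diff(c) <= 0):
                raise ValueError(f"{name} coordinates must be increasing")

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def ny(self) -> int:
        return self.y.size

    @property
    def L(self) -> float:
        return float(self.x[-1])

    @property
    def H(self) -> float:
        return float(self.y[-1])

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y)

    @property
    def wx(self) -> np.ndarray:
        """Lateral dual-cell widths (trapezoid weights over x)."""
        dx = self.dx
        w = np.empty(self.nx)
        w[0] = 0.5 * dx[0]
        w[-1] = 0.5 * dx[-1]
        w[1:-1] = 0.5 * (dx[:-1] + dx[1:])
        return w

    @property
    def wy(self) -> np.ndarray:
        """Vertical dual-cell widths."""
        dy = self.dy
        w = np.empty(self.ny)
        w[0] = 0.5 * dy[0]
        w[-1] = 0.5 * dy[-1]
        w[1:-1] = 0.5 * (dy[:-1] + dy[1:])
        return w

    @property
    def grid1d(self) -> Grid1D:
        return Grid1D(y=self.y)


def make_grid(L: float, H: float, nx: int = 64, ny: int = 160,
              ratio: float = 1.05, min_cells_near_wall: int = 30,
              near_wall_depth: float = 5e-6) -> Grid2D:
    """Default simulation grid.

    The stretched vertical grid must resolve the near-surface region: at
    least ``min_cells_near_wall`` cells within ``near_wall_depth`` of y = 0.
    """
    y = stretched_nodes(H, ny, ratio)
    g = Grid2D(x=np.linspace(0.0, L, nx + 1), y=y)
    got = g.grid1d.cells_within(min(near_wall_depth, H))
    if near_wall_depth < H and got < min_cells_near_wall:
        raise ValueError(
            f"grid too coarse near the surface: {got} cells within "
            f"{near_wall_depth:g} m, need >= {min_cells_near_wall}"
        )
    return g
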