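"""Open-loop sensorimotor environment: sensory change over (position, velocity).

With the motor loop cut, velocity becomes a freely chosen command and the
sensory consequence of issuing it at position ``p`` is

    S(p, v) = v * ds/dp(p)

— the rate of sensory change produced by moving at ``v`` through the static
field.  This surface is a property of body and world alone (no controller
parameters enter).  For an isolated symmetric object it obeys the law
``S(c + d, v) = S(c - d, -v)`` and features two peaks and two troughs at the
points of greatest field slope, one pair per direction of travel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import World, sense_gradient

__all__ = [
    "SMEnvironmentSurface",
    "compute_surface",
    "find_extrema",
    "check_symmetry",
    "default_grids",
]


@dataclass(frozen=True)
class SMEnvironmentSurface:
    """S(p, v) sampled on a rectangular grid; ``values[i, j] = S(p[i], v[j])``."""

    p_grid: np.ndarray
    v_grid: np.ndarray
    values: np.ndarray
    world: World

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns p, v, value."""
        P, V = np.meshgrid(self.p_grid, self.v_grid, indexing="ij")
        return pd.DataFrame({
            "p": P.ravel(), "v": V.ravel(), "value": self.values.ravel(),
        })

    def save_matrix(self, csv_path, header_path) -> None:
        """Dense-matrix export: value matrix CSV plus a JSON grid header."""
        import json
        from pathlib import Path

        np.savetxt(csv_path, self.values, delimiter=",", fmt="%.17g")
        doc = {"p_grid": self.p_grid.tolist(), "v_grid": self.v_grid.tolist(),
               "world": self.world.to_dict(),
               "matrix_csv": str(Path(csv_path).name)}
        Path(header_path).write_text(json.dumps(doc, indent=2))


def default_grids(world: World, p_step: float = 0.01, v_step: float = 0.01,
                  v_abs: float = 1.0):
    """Grids spanning +/- 3 widths around the first object, |v| <= v_abs."""
    if not world.objects:
        raise ValueError("default grids need at least one object")
    o = world.objects[0]
    wmax = max(obj.width for obj in world.objects)
    half = 3.0 * wmax
    n_p = int(round(2 * half / p_step))
    n_v = int(round(2 * v_abs / v_step))
    p_grid = o.center + np.linspace(-half, half, n_p + 1)
    v_grid = np.linspace(-v_abs, v_abs, n_v + 1)
    return p_grid, v_grid


def compute_surface(world: World, p_grid, v_grid) -> SMEnvironmentSurface:
    """Evaluate S(p, v) = v * ds/dp(p) on the grid.  Pure and deterministic."""
    p_grid = np.asarray(p_grid, dtype=float)
    v_grid = np.asarray(v_grid, dtype=float)
    if p_grid.size == 0 or v_grid.size == 0:
        raise ValueError("grids must be nonempty")
    grad = sense_gradient(world, p_grid)
    values = np.outer(np.atleast_1d(grad), v_grid)
    return SMEnvironmentSurface(p_grid, v_grid, values, world)


def find_extrema(surface: SMEnvironmentSurface) -> list[dict]:
    """Grid-local extrema of the surface (8-neighbor, strict comparison).

    Boundary cells participate (missing neighbors are ignored); cells on the
    zero plateau of the background are excluded so that flat regions never
    produce spurious extrema.  Returns dicts with keys p, v, value, kind.
    """
    Z = surface.values
    n, m = Z.shape
    pad_max = np.full((n + 2, m + 2), -np.inf)
    pad_min = np.full((n + 2, m + 2), np.inf)
    pad_max[1:-1, 1:-1] = Z
    pad_min[1:-1, 1:-1] = Z

    is_max = np.ones_like(Z, dtype=bool)
    is_min = np.ones_like(Z, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb_max = pad_max[1 + di:n + 1 + di, 1 + dj:m + 1 + dj]
            nb_min = pad_min[1 + di:n + 1 + di, 1 + dj:m + 1 + dj]
            is_max &= Z > nb_max
            is_min &= Z < nb_min
    nonzero = Z != 0.0
    is_max &= nonzero
    is_min &= nonzero

    out = []
    for kind, mask in (("peak", is_max), ("trough", is_min)):
        for i, j in zip(*np.nonzero(mask)):
            out.append({
                "p": float(surface.p_grid[i]),
                "v": float(surface.v_grid[j]),
                "value": float(Z[i, j]),
                "kind": kind,
            })
    out.sort(key=lambda e: (e["p"], e["v"]))
    return out


def check_symmetry(surface: SMEnvironmentSurface, center: float,
                   atol: float = 1e-9) -> float:
    """Worst-case violation of S(c + d, v) = S(c - d, -v) over the grid.

    Requires grids symmetric about ``center`` (positions) and 0 (velocities);
    an asymmetric grid is a usage error.
    """
    p = surface.p_grid
    v = surface.v_grid
    if not np.allclose((p - center), -(p - center)[::-1], atol=atol):
        raise ValueError("position grid is not symmetric about the center")
    if not np.allclose(v, -v[::-1], atol=atol):
        raise ValueError("velocity grid is not symmetric about zero")
    mirrored = surface.values[::-1, ::-1]
    return float(np.max(np.abs(surface.values - mirrored)))
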