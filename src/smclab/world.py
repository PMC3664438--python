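"""Circular 1-D environment built from bell-shaped (Gaussian) objects.

The environment is a ring of circumference ``L`` carrying a static scalar
field: each object contributes ``h * exp(-d^2 / (2 w^2))`` where ``d`` is the
wrapped distance to the object's center.  The agent's single distance sensor
reads the field height at its own position, clipped to 1 ("normalized
proximity").  Narrow and wide objects of comparable height can therefore be
told apart only through movement: the instantaneous reading never identifies
the shape, but the sensory *change* under self-motion does.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "GaussianObject",
    "World",
    "wrap",
    "wrapped_distance",
    "sense",
    "sense_gradient",
    "load_world",
    "save_world",
]

#: Default ring circumference (world units).
DEFAULT_CIRCUMFERENCE = 40.0
#: Canonical shape widths: narrow (approach target) and wide (avoid target).
NARROW_WIDTH = 1.0
WIDE_WIDTH = 3.0
#: Heights are drawn from this interval per trial so that shapes differ only
#: in steepness and horizontal extent, never reliably in peak height.
HEIGHT_RANGE = (0.5, 1.0)


def wrap(p, L):
    """Map position(s) ``p`` onto the ring ``[0, L)``."""
    if L <= 0:
        raise ValueError(f"circumference must be positive, got L={L}")
    r = np.asarray(p) % L if isinstance(p, np.ndarray) else p % L
    # rounding can land exactly on L for tiny negative inputs
    if isinstance(r, np.ndarray):
        return np.where(r == L, 0.0, r)
    return 0.0 if r == L else r


def wrapped_distance(p1, p2, L):
    """Signed minimal ring distance of ``p1`` relative to ``p2``.

    The result lies in ``(-L/2, L/2]``; it is antisymmetric in its
    arguments except exactly at the antipode, where the sign is fixed
    positive by convention.
    """
    if L <= 0:
        raise ValueError(f"circumference must be positive, got L={L}")
    half = 0.5 * L
    res = half - (half - (np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float))) % L
    return float(res) if res.ndim == 0 else res


@dataclass(frozen=True)
class GaussianObject:
    """A bell-shaped object: height ``h`` in (0, 1], width ``w`` > 0."""

    center: float
    height: float
    width: float

    def __post_init__(self):
        if not (0.0 < self.height <= 1.0):
            raise ValueError(f"height must lie in (0, 1], got {self.height}")
        if not self.width > 0.0:
            raise ValueError(f"width must be positive, got {self.width}")

    def to_dict(self) -> dict:
        return {"center": self.center, "height": self.height, "width": self.width}


@dataclass(frozen=True)
class World:
    """A ring of circumference ``L`` with a list of Gaussian objects.

    Analyses downstream assume effectively isolated shapes; if two object
    centers come closer than six times the largest width a warning (not an
    error) is raised, because field clipping and overlap would then blur
    the single-shape semantics.
    """

    circumference: float = DEFAULT_CIRCUMFERENCE
    objects: tuple[GaussianObject, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.circumference > 0:
            raise ValueError(
                f"circumference must be positive, got {self.circumference}"
            )
        objs = tuple(self.objects)
        object.__setattr__(self, "objects", objs)
        for o in objs:
            if not (0.0 <= o.center < self.circumference):
                raise ValueError(
                    f"center must lie in [0, {self.circumference}), got {o.center}"
                )
        if len(objs) >= 2:
            wmax = max(o.width for o in objs)
            for i in range(len(objs)):
                for j in range(i + 1, len(objs)):
                    sep = abs(
                        wrapped_distance(
                            objs[i].center, objs[j].center, self.circumference
                        )
                    )
                    if sep < 6.0 * wmax:
                        warnings.warn(
                            "object centers closer than 6*max(width): "
                            "single-shape analyses may be unreliable",
                            stacklevel=2,
                        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "circumference": self.circumference,
            "objects": [o.to_dict() for o in self.objects],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "World":
        try:
            objs = tuple(
                GaussianObject(o["center"], o["height"], o["width"])
                for o in d.get("objects", ())
            )
            return cls(circumference=d["circumference"], objects=objs)
        except KeyError as exc:
            raise ValueError(f"world document missing key {exc.args[0]!r}") from exc

    @classmethod
    def single(cls, width: float, height: float, L: float = DEFAULT_CIRCUMFERENCE,
               center: float | None = None) -> "World":
        """A single-shape world with the object at mid-ring by default."""
        c = 0.5 * L if center is None else center
        return cls(circumference=L, objects=(GaussianObject(c, height, width),))


def sense(world: World, p) -> float:
    """Normalized proximity reading at position ``p``.

    Sum of object contributions with wrapped distances, clipped to 1.
    Accepts a scalar or an array of positions.
    """
    p = np.asarray(p, dtype=float)
    total = np.zeros_like(p)
    for o in world.objects:
        d = wrapped_distance(p, o.center, world.circumference)
        total = total + o.height * np.exp(-(d * d) / (2.0 * o.width**2))
    out = np.minimum(1.0, total)
    return float(out) if out.ndim == 0 else out


def sense_gradient(world: World, p):
    """Spatial derivative ds/dp of the sensed field at ``p``.

    Analytic differentiation of the summed field; where the field is
    clipped at 1 the derivative is 0.  Antisymmetric about each isolated
    object's center.
    """
    p = np.asarray(p, dtype=float)
    total = np.zeros_like(p)
    grad = np.zeros_like(p)
    for o in world.objects:
        d = wrapped_distance(p, o.center, world.circumference)
        g = o.height * np.exp(-(d * d) / (2.0 * o.width**2))
        total = total + g
        grad = grad - (d / o.width**2) * g
    grad = np.where(total >= 1.0, 0.0, grad)
    return float(grad) if grad.ndim == 0 else grad


def field_profile(world: World, n: int = 4001) -> np.ndarray:
    """Sampled field: array of (position, sensor_value) rows."""
    p = np.linspace(0.0, world.circumference, n, endpoint=False)
    return np.column_stack([p, sense(world, p)])


# -- file I/O ----------------------------------------------------------

def save_world(world: World, path) -> None:
    path = Path(path)
    doc = world.to_dict()
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def load_world(path) -> World:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    return World.from_dict(doc)
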