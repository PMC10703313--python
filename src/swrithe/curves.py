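"""Discrete 3D curves and synthetic generators.

The central object is :class:`DiscreteCurve`, an ordered sequence of 3D
points (in Angstroms) representing a protein C-alpha backbone or any
smoothed/synthetic polyline.  The generators in this module produce the
reference curves (helices, an open trefoil, equilateral random walks and
mock labeled backbones) used throughout the test-suite as geometric
oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DiscreteCurve",
    "make_helix",
    "make_trefoil",
    "make_random_walk",
    "make_mock_backbone",
]

#: Two consecutive points closer than this are considered coincident.
MIN_SEPARATION = 1e-9

#: Canonical consecutive C-alpha spacing (Angstrom).
CA_STEP = 3.8


@dataclass(frozen=True)
class DiscreteCurve:
    """An ordered open polyline in 3-space.

    Parameters
    ----------
    points:
        Array-like of shape ``(n, 3)`` with ``n >= 2``; consecutive points
        must be separated by more than ``MIN_SEPARATION``.
    label:
        Free-text identifier.
    breaks:
        Edge indices (0-based, edge ``k`` joins points ``k`` and ``k+1``)
        flagged as chain breaks.  Downstream smoothing treats a flagged
        edge as an immovable section boundary.
    """

    points: np.ndarray
    label: str = ""
    breaks: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("a curve needs at least 2 points")
        seps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seps <= MIN_SEPARATION):
            bad = int(np.argmax(seps <= MIN_SEPARATION))
            raise ValueError(f"consecutive points {bad} and {bad + 1} coincide")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "breaks", frozenset(int(b) for b in self.breaks))

    # -- basic geometry -------------------------------------------------

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_edges(self) -> int:
        return self.points.shape[0] - 1

    def __len__(self) -> int:
        return self.n_points

    @property
    def edge_vectors(self) -> np.ndarray:
        return np.diff(self.points, axis=0)

    def sliced(self, start: int, stop: int, label: str | None = None) -> "DiscreteCurve":
        """Sub-curve over point indices ``start..stop`` (0-based inclusive)."""
        if not (0 <= start < stop <= self.n_points - 1):
            raise ValueError(f"invalid slice [{start}, {stop}]")
        pts = self.points[start : stop + 1]
        brk = frozenset(b - start for b in self.breaks if start <= b < stop)
        return DiscreteCurve(pts, label or self.label, brk)

    def mirrored(self) -> "DiscreteCurve":
        """Mirror image (x negated): reverses chirality."""
        pts = self.points.copy()
        pts[:, 0] *= -1.0
        return DiscreteCurve(pts, self.label + "|mirror", self.breaks)

    def reversed(self) -> "DiscreteCurve":
        n_e = self.n_edges
        brk = frozenset(n_e - 1 - b for b in self.breaks)
        return DiscreteCurve(self.points[::-1].copy(), self.label + "|rev", brk)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] | None = None,
                    scale: float = 1.0) -> "DiscreteCurve":
        pts = self.points * float(scale)
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return DiscreteCurve(pts, self.label, self.breaks)

    # -- serialization --------------------------------------------------

    def to_xyz(self) -> str:
        """Whitespace-delimited text, one ``x y z`` triple per line."""
        return "\n".join(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in self.points) + "\n"

    @classmethod
    def from_xyz(cls, text: str, label: str = "") -> "DiscreteCurve":
        rows = [line.split() for line in text.splitlines() if line.strip()]
        pts = np.array([[float(v) for v in r[:3]] for r in rows], dtype=float)
        return cls(pts, label)

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "points": [[round(float(v), 6) for v in p] for p in self.points],
                "breaks": sorted(self.breaks),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscreteCurve":
        obj = json.loads(text)
        return cls(np.asarray(obj["points"], dtype=float), obj.get("label", ""),
                   frozenset(obj.get("breaks", [])))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_helix(radius: float, pitch: float, points_per_turn: int,
               n_turns: float, label: str = "helix") -> DiscreteCurve:
    """Uniform discrete helix ``x(t) = (R cos t, R sin t, P t / 2pi)``.

    Positive pitch yields a right-handed coil of positive writhe (matching
    the closed-form per-turn value); negate one coordinate via
    :meth:`DiscreteCurve.mirrored` for the opposite chirality.
    """
    if radius < 0 or pitch < 0:
        raise ValueError("radius and pitch must be non-negative")
    if radius == 0 and pitch == 0:
        raise ValueError("degenerate helix: radius and pitch both zero")
    if points_per_turn < 3:
        raise ValueError("need at least 3 points per turn")
    if n_turns <= 0:
        raise ValueError("n_turns must be positive")
    n = math.ceil(points_per_turn * n_turns) + 1
    t = 2.0 * math.pi * np.arange(n) / float(points_per_turn)
    pts = np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), pitch * t / (2.0 * math.pi)]
    )
    return DiscreteCurve(pts, label)


def make_trefoil(n_points: int, scale: float = 1.0, label: str = "trefoil") -> DiscreteCurve:
    """Open discretization of the (2,3) torus knot.

    ``x(t) = scale * (sin t + 2 sin 2t, cos t - 2 cos 2t, -sin 3t)`` for
    ``t`` in ``[0, 2pi)``; the last sample stops one step short of the
    first so the curve has distinct endpoints.
    """
    if n_points < 30:
        raise ValueError("need at least 30 points for a faithful trefoil")
    t = 2.0 * math.pi * np.arange(n_points) / float(n_points)
    pts = scale * np.column_stack(
        [np.sin(t) + 2.0 * np.sin(2.0 * t),
         np.cos(t) - 2.0 * np.cos(2.0 * t),
         -np.sin(3.0 * t)]
    )
    return DiscreteCurve(pts, label)


def make_random_walk(n_points: int, step: float = 1.0, seed: int = 0,
                     label: str = "walk") -> DiscreteCurve:
    """Equilateral random walk with steps uniform on the sphere."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_points - 1, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = np.vstack([np.zeros(3), np.cumsum(step * dirs, axis=0)])
    return DiscreteCurve(pts, label)


# -- mock labeled backbone ---------------------------------------------------

# Canonical local geometry (Angstrom): alpha-helix radius/rise, strand rise.
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = 2.0 * math.pi / 3.6
_STRAND_RISE = 3.3
# Zigzag amplitude chosen so strand CA-CA spacing is exactly CA_STEP.
_STRAND_WOBBLE = 0.5 * math.sqrt(CA_STEP ** 2 - _STRAND_RISE ** 2)
_CLASH_RADIUS = 1.0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _helix_local(n: int) -> np.ndarray:
    k = np.arange(n)
    pts = np.column_stack(
        [_HELIX_RADIUS * np.sin(k * _HELIX_TURN),
         _HELIX_RADIUS * np.cos(k * _HELIX_TURN),
         _HELIX_RISE * k]
    )
    return pts - pts[0]


def _strand_local(n: int) -> np.ndarray:
    k = np.arange(n)
    pts = np.column_stack(
        [_STRAND_WOBBLE * (-1.0) ** k, np.zeros(n), _STRAND_RISE * k]
    )
    return pts - pts[0]


def make_mock_backbone(sse_spec: Sequence[tuple[str, int]], seed: int = 0,
                       label: str = "mock", max_restarts: int = 25):
    """Synthetic C-alpha backbone with aligned secondary-structure labels.

    ``sse_spec`` is an ordered list of ``(label, residue_count)`` pairs with
    labels in ``{"H", "E", "C"}``.  H sections follow ideal alpha-helix
    geometry, E sections are near-straight zigzags and C sections are
    self-avoiding random linkers (1 Angstrom clash radius).  Returns a
    ``(DiscreteCurve, SSAssignment)`` pair; deterministic for a fixed seed.
    """
    from .pdb_io import SSAssignment  # local import avoids a cycle

    if not sse_spec:
        raise ValueError("empty sse_spec")
    for lab, count in sse_spec:
        if lab not in ("H", "E", "C"):
            raise ValueError(f"unknown SSE label {lab!r}")
        if count < 1:
            raise ValueError("residue_count must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        pts = _try_build_backbone(sse_spec, rng)
        if pts is not None:
            labels = "".join(lab * count for lab, count in sse_spec)
            return DiscreteCurve(pts, label), SSAssignment(labels)
    raise RuntimeError("could not build a self-avoiding mock backbone; "
                       "try another seed or a shorter linker")


def _try_build_backbone(sse_spec, rng) -> np.ndarray | None:
    pts: list[np.ndarray] = []
    for lab, count in sse_spec:
        if pts:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            start = pts[-1] + CA_STEP * direction
        else:
            start = np.zeros(3)
        if lab == "C":
            section = _build_linker(start, count, pts, rng)
            if section is None:
                return None
        else:
            local = _helix_local(count) if lab == "H" else _strand_local(count)
            section = start + local @ _random_rotation(rng).T
        pts.extend(section)
    return np.asarray(pts)


def _build_linker(start, count, existing, rng, max_tries: int = 60):
    arr = np.asarray(existing).reshape(-1, 3) if len(existing) else np.zeros((0, 3))
    section = [start]
    for _ in range(count - 1):
        for _try in range(max_tries):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            cand = section[-1] + CA_STEP * d
            prior = np.vstack([arr] + [p[None, :] for p in section[:-1]])
            if prior.shape[0] == 0 or \
                    np.min(np.linalg.norm(prior - cand, axis=1)) >= _CLASH_RADIUS:
                section.append(cand)
                break
        else:
            return None
    return section
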