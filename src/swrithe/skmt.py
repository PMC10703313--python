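"""Secondary-structure-aware backbone smoothing.

Each maximal secondary-structure run is reduced locally: the middle point
of three consecutive surviving points may be removed only when the
triangle they span is not intersected by any edge of the current working
curve (other than the two edges being merged).  Section boundary residues
are never removed, so the output marks every SSE boundary while keeping
any linker points needed to preserve threading, and hence the curve's
entanglement.

The number of points of the smoothed curve is the length coordinate used
by the empirical entanglement bounds.
"""

from __future__ import annotations

import json

import numpy as np

from .curves import DiscreteCurve
from .pdb_io import LabeledBackbone, write_ca_pdb

__all__ = [
    "SmoothedCurve",
    "segment_triangle_intersects",
    "skmt",
    "skmt_length",
]

EPS = 1e-9


class SmoothedCurve:
    """Output of the smoothing: points plus per-point residue provenance."""

    def __init__(self, curve: DiscreteCurve, provenance, source: str = ""):
        prov = np.asarray(provenance, dtype=int)
        if prov.shape != (curve.n_points,):
            raise ValueError("provenance must give one residue index per point")
        if np.any(np.diff(prov) <= 0):
            raise ValueError("provenance indices must be strictly increasing")
        self.curve = curve
        self.provenance = prov
        self.source = source

    @property
    def skmt_length(self) -> int:
        return self.curve.n_points

    def __len__(self) -> int:
        return self.skmt_length

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "skmt_length": self.skmt_length,
                "provenance": self.provenance.tolist(),
                "points": [
                    [round(float(v), 6) for v in p] for p in self.curve.points
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SmoothedCurve":
        obj = json.loads(text)
        return cls(
            DiscreteCurve(np.asarray(obj["points"], dtype=float), obj.get("source", "")),
            obj["provenance"],
            obj.get("source", ""),
        )

    def to_xyz(self) -> str:
        return self.curve.to_xyz()

    def to_pdb(self) -> str:
        return write_ca_pdb(self.curve)


def skmt_length(smoothed: SmoothedCurve) -> int:
    """Number of points of the smoothed curve."""
    return smoothed.skmt_length


# ---------------------------------------------------------------------------
# geometric predicate
# ---------------------------------------------------------------------------


def _triangle_hits(a, b, c, P, Q, eps: float = EPS) -> np.ndarray:
    """Vectorized: does each open segment ``P[k] -> Q[k]`` meet triangle abc?

    The triangle is closed (touching counts); the segments are open at
    their endpoints.  A degenerate triangle never reports intersection.
    """
    P = np.atleast_2d(P)
    Q = np.atleast_2d(Q)
    out = np.zeros(P.shape[0], dtype=bool)

    ab = b - a
    ac = c - a
    n = np.cross(ab, ac)
    nn = np.linalg.norm(n)
    scale = max(np.linalg.norm(ab), np.linalg.norm(ac), 1.0)
    if nn <= eps * scale * scale:
        return out  # degenerate triangle
    n = n / nn

    d1 = (P - a) @ n
    d2 = (Q - a) @ n
    coplanar = (np.abs(d1) <= eps) & (np.abs(d2) <= eps)
    same_side = ((d1 > eps) & (d2 > eps)) | ((d1 < -eps) & (d2 < -eps))
    crossing = ~coplanar & ~same_side

    if crossing.any():
        idx = np.nonzero(crossing)[0]
        denom = d1[idx] - d2[idx]
        denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
        t = d1[idx] / denom
        seg = Q[idx] - P[idx]
        seg_len = np.linalg.norm(seg, axis=1)
        t_eps = eps / np.maximum(seg_len, eps)
        valid = (t > t_eps) & (t < 1.0 - t_eps)
        x = P[idx] + t[:, None] * seg
        # barycentric coordinates via the plane's metric
        d00 = ab @ ab
        d01 = ab @ ac
        d11 = ac @ ac
        det = d00 * d11 - d01 * d01
        xa = x - a
        dx0 = xa @ ab
        dx1 = xa @ ac
        u = (d11 * dx0 - d01 * dx1) / det
        v = (d00 * dx1 - d01 * dx0) / det
        tol = eps / max(np.sqrt(d00), np.sqrt(d11))
        inside = (u >= -tol) & (v >= -tol) & (u + v <= 1.0 + tol)
        out[idx] = valid & inside

    if coplanar.any():
        out[np.nonzero(coplanar)[0]] = _coplanar_hits(
            a, b, c, n, P[coplanar], Q[coplanar], eps
        )
    return out


def _coplanar_hits(a, b, c, n, P, Q, eps) -> np.ndarray:
    """2D overlap test for segments lying in the triangle's plane."""
    from shapely.geometry import LineString, Polygon

    e1 = b - a
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    def to2d(p):
        rel = p - a
        return np.column_stack([rel @ e1, rel @ e2])

    tri = Polygon(to2d(np.vstack([a, b, c])))
    res = np.zeros(P.shape[0], dtype=bool)
    for k, (p, q) in enumerate(zip(to2d(P), to2d(Q))):
        d = q - p
        ln = np.hypot(*d)
        if ln <= 2 * eps:
            continue
        shrink = (eps / ln) * d
        res[k] = LineString([p + shrink, q - shrink]).intersects(tri)
    return res


def segment_triangle_intersects(a, b, c, p, q, eps: float = EPS) -> bool:
    """True iff the open segment (p, q) meets the closed triangle (a, b, c)."""
    a, b, c, p, q = (np.asarray(v, dtype=float) for v in (a, b, c, p, q))
    return bool(_triangle_hits(a, b, c, p[None, :], q[None, :], eps)[0])


# ---------------------------------------------------------------------------
# the smoothing algorithm
# ---------------------------------------------------------------------------


def _sections_with_breaks(backbone: LabeledBackbone) -> list[tuple[int, int]]:
    """Section spans as (start, end) residue-index pairs.

    Adjacent sections share their boundary residue (the last residue of
    each SSE run), so the smoothed curve stays connected and every SSE
    boundary is retained.  Chain-break edges add immovable boundaries on
    both sides of the broken edge.
    """
    bounds = {0, backbone.curve.n_points - 1}
    for _, _s, e in backbone.ss.sections:
        bounds.add(e)
    for edge in backbone.curve.breaks:
        bounds.add(edge)
        bounds.add(edge + 1)
    marks = sorted(bounds)
    return [(marks[k], marks[k + 1]) for k in range(len(marks) - 1)]


def skmt(backbone: LabeledBackbone) -> SmoothedCurve:
    """Reduce each secondary-structure section to its minimal pierced-safe form.

    Sections are processed N-to-C.  Within a section, repeated left-to-right
    passes remove the middle point of any consecutive triple whose triangle
    is not intersected by any edge of the current working curve, until a
    full pass makes no removal.  Section endpoints (shared between adjacent
    sections) and chain-break endpoints are never removed.
    """
    pts = backbone.curve.points
    n = pts.shape[0]
    surviving = list(range(n))

    for sec_start, sec_end in _sections_with_breaks(backbone):
        changed = True
        while changed:
            changed = False
            pos = 1
            while pos < len(surviving) - 1:
                b = surviving[pos]
                if not (sec_start < b < sec_end):
                    pos += 1
                    continue
                ia, ic = surviving[pos - 1], surviving[pos + 1]
                if _removable(pts, surviving, pos, ia, b, ic):
                    surviving.pop(pos)
                    changed = True
                else:
                    pos += 1

    coords = pts[np.asarray(surviving)]
    curve = DiscreteCurve(coords, backbone.curve.label + "|skmt")
    return SmoothedCurve(curve, surviving, backbone.source or backbone.curve.label)


def _removable(pts, surviving, pos, ia, ib, ic) -> bool:
    work = pts[np.asarray(surviving)]
    P = work[:-1]
    Q = work[1:]
    keep = np.ones(P.shape[0], dtype=bool)
    keep[pos - 1] = False  # edge (a, b)
    keep[pos] = False      # edge (b, c)
    if not keep.any():
        return True
    hits = _triangle_hits(pts[ia], pts[ib], pts[ic], P[keep], Q[keep])
    return not hits.any()
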