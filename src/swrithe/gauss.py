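"""Discrete Gauss-integral machinery: writhe, average crossing number and
the all-subsection fingerprint.

The elementary quantity is the signed solid angle ``omega`` subtended by a
pair of oriented segments (the Klenin--Langowski spherical-area form).
Summing ``2 * Omega / 4pi`` over non-adjacent edge pairs of a discrete
curve yields its writhe; the unsigned sum yields the average crossing
number.  Subsection values for every window of at least 6 points are
assembled in O(n^2) total via 2D prefix sums over the pairwise Omega
matrix.

A Monte-Carlo projection-counting estimator (average signed/unsigned
crossings over random viewing directions) is provided as an independent
oracle for both quantities.
"""

from __future__ import annotations

import json
import math
from typing import NamedTuple

import numpy as np

from .curves import DiscreteCurve

__all__ = [
    "omega",
    "omega_matrix",
    "writhe",
    "acn",
    "Fingerprint",
    "fingerprint",
    "mc_projection_estimate",
    "projected_crossings",
]

FOUR_PI = 4.0 * math.pi

#: Cross products with norm below this are treated as degenerate
#: (coplanar geometry) and contribute exactly zero.
DEGENERATE_EPS = 1e-12

#: Shortest subsection with a defined fingerprint entry: end - start >= 5
#: in 1-based point indices, i.e. at least 6 points.
MIN_SPAN = 5


def _normalize_rows(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    ok = n[..., 0] > DEGENERATE_EPS
    safe = np.where(n > DEGENERATE_EPS, n, 1.0)
    return v / safe, ok


def _omega_pairs(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized signed solid angle for stacked segment pairs."""
    r12 = p2 - p1
    r34 = p4 - p3
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2

    n1, ok1 = _normalize_rows(np.cross(r13, r14))
    n2, ok2 = _normalize_rows(np.cross(r14, r24))
    n3, ok3 = _normalize_rows(np.cross(r24, r23))
    n4, ok4 = _normalize_rows(np.cross(r23, r13))
    ok = ok1 & ok2 & ok3 & ok4

    def asin_dot(a, b):
        return np.arcsin(np.clip(np.einsum("...k,...k->...", a, b), -1.0, 1.0))

    area = asin_dot(n1, n2) + asin_dot(n2, n3) + asin_dot(n3, n4) + asin_dot(n4, n1)
    sign = np.sign(np.einsum("...k,...k->...", np.cross(r34, r12), r13))
    return np.where(ok, area * sign, 0.0)


def omega(p1, p2, p3, p4) -> float:
    """Signed solid angle contributed by the ordered edges (p1,p2), (p3,p4).

    ``omega / 4pi`` is the pair's Gauss-integral contribution.  Pairs that
    share an endpoint or are coplanar (any normalization denominator below
    ``1e-12``) contribute exactly zero.  Zero-length edges are rejected.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    if np.linalg.norm(p2 - p1) <= DEGENERATE_EPS or \
       np.linalg.norm(p4 - p3) <= DEGENERATE_EPS:
        raise ValueError("degenerate (zero-length) edge")
    for a in (p1, p2):
        for b in (p3, p4):
            if np.linalg.norm(a - b) <= DEGENERATE_EPS:
                return 0.0
    return float(_omega_pairs(p1, p2, p3, p4))


def omega_matrix(curve: DiscreteCurve) -> np.ndarray:
    """Symmetric matrix of Omega values over all edge pairs.

    Adjacent pairs (shared endpoint) and the diagonal are zero.
    """
    pts = curve.points
    e = curve.n_edges
    om = np.zeros((e, e))
    l, m = np.triu_indices(e, k=2)
    if l.size:
        vals = _omega_pairs(pts[l], pts[l + 1], pts[m], pts[m + 1])
        om[l, m] = vals
        om[m, l] = vals
    return om


def _require_points(curve: DiscreteCurve, n: int) -> None:
    if curve.n_points < n:
        raise ValueError(
            f"need at least {n} points for a meaningful calculation, "
            f"got {curve.n_points}"
        )


def writhe(curve: DiscreteCurve) -> float:
    """Discrete writhe: ``2 * sum_{l<m} Omega_lm / 4pi``."""
    _require_points(curve, 5)
    return float(omega_matrix(curve).sum() / FOUR_PI)


def acn(curve: DiscreteCurve) -> float:
    """Average crossing number: the unsigned analogue of the writhe."""
    _require_points(curve, 5)
    return float(np.abs(omega_matrix(curve)).sum() / FOUR_PI)


# ---------------------------------------------------------------------------
# fingerprint
# ---------------------------------------------------------------------------


class Fingerprint:
    """Writhe and acn of every subsection spanning at least ``MIN_SPAN``.

    Entries are addressed with the 1-based inclusive convention
    ``wr(i, n)`` for ``1 <= i <= j - 5`` and ``i + 5 <= n <= j`` where
    ``j`` is the number of points.
    """

    def __init__(self, wr_table: np.ndarray, acn_table: np.ndarray, label: str = ""):
        self._wr = wr_table
        self._acn = acn_table
        self.label = label

    @property
    def n_points(self) -> int:
        return self._wr.shape[0]

    def _check(self, i: int, n: int) -> tuple[int, int]:
        j = self.n_points
        if not (1 <= i <= j - MIN_SPAN and i + MIN_SPAN <= n <= j):
            raise KeyError(f"subsection ({i}, {n}) undefined for {j} points")
        return i - 1, n - 1

    def wr(self, i: int, n: int) -> float:
        a, b = self._check(i, n)
        return float(self._wr[a, b])

    def acn(self, i: int, n: int) -> float:
        a, b = self._check(i, n)
        return float(self._acn[a, b])

    def profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative writhe profile: lengths ``n = 6..j`` and ``wr(1, n)``."""
        j = self.n_points
        ns = np.arange(MIN_SPAN + 1, j + 1)
        return ns, self._wr[0, MIN_SPAN:].copy()

    def items(self):
        j = self.n_points
        for i in range(1, j - MIN_SPAN + 1):
            for n in range(i + MIN_SPAN, j + 1):
                yield i, n, float(self._wr[i - 1, n - 1]), float(self._acn[i - 1, n - 1])

    def to_csv(self) -> str:
        lines = ["i,n,wr,acn"]
        lines += [f"{i},{n},{w:.10g},{a:.10g}" for i, n, w, a in self.items()]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "n_points": self.n_points,
                "entries": [
                    {"i": i, "n": n, "wr": round(w, 6), "acn": round(a, 6)}
                    for i, n, w, a in self.items()
                ],
            }
        )


def fingerprint(curve: DiscreteCurve) -> Fingerprint:
    """All-subsection writhe/acn table in O(n^2) via 2D prefix sums."""
    _require_points(curve, MIN_SPAN + 1)
    om = omega_matrix(curve)
    j = curve.n_points

    def block_sums(mat: np.ndarray) -> np.ndarray:
        # P[r, c] = sum of mat[:r, :c]
        p = np.zeros((mat.shape[0] + 1, mat.shape[1] + 1))
        p[1:, 1:] = mat.cumsum(0).cumsum(1)
        out = np.full((j, j), np.nan)
        # subsection of points a..b (0-based) uses edges a..b-1
        for a in range(0, j - MIN_SPAN):
            bs = np.arange(a + MIN_SPAN, j)
            # square block [a..b-1] x [a..b-1]; symmetric matrix counts
            # each unordered pair twice, so wr = block / 4pi
            out[a, bs] = (
                p[bs, bs] - p[a, bs] - p[bs, a] + p[a, a]
            )
        return out / FOUR_PI

    return Fingerprint(block_sums(om), block_sums(np.abs(om)), curve.label)


# ---------------------------------------------------------------------------
# Monte-Carlo projection oracle
# ---------------------------------------------------------------------------


class MCEstimate(NamedTuple):
    writhe: float
    acn: float
    writhe_se: float
    acn_se: float


def _nonadjacent_pairs(n_edges: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_edges, k=2)


def projected_crossings(curve: DiscreteCurve, direction) -> list[tuple[int, int, int]]:
    """Signed crossings of the projection along ``direction``.

    Returns ``(l, m, sign)`` for every non-adjacent edge pair whose
    projections cross, ordered by edge indices.  The sign is that of the
    Gauss integrand at the crossing chord.
    """
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    # orthonormal basis of the projection plane
    a = np.array([1.0, 0.0, 0.0])
    if abs(u @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)

    pts = curve.points
    p2d = np.column_stack([pts @ v, pts @ w])
    l, m = _nonadjacent_pairs(curve.n_edges)
    if not l.size:
        return []

    a1, a2 = p2d[l], p2d[l + 1]
    b1, b2 = p2d[m], p2d[m + 1]

    def cross2(p, q):
        return p[:, 0] * q[:, 1] - p[:, 1] * q[:, 0]

    da = a2 - a1
    db = b2 - b1
    denom = cross2(da, db)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross2(b1 - a1, db) / denom
        s = cross2(b1 - a1, da) / denom
    hit = (np.abs(denom) > 0) & (t > 0) & (t < 1) & (s > 0) & (s < 1)
    if not hit.any():
        return []

    li, mi, ti, si = l[hit], m[hit], t[hit], s[hit]
    xa = pts[li] + ti[:, None] * (pts[li + 1] - pts[li])
    xb = pts[mi] + si[:, None] * (pts[mi + 1] - pts[mi])
    tan_a = pts[li + 1] - pts[li]
    tan_b = pts[mi + 1] - pts[mi]
    signs = np.sign(np.einsum("ij,ij->i", np.cross(tan_a, tan_b), xa - xb))
    order = np.lexsort((mi, li))
    return [(int(li[k]), int(mi[k]), int(signs[k])) for k in order]


def mc_projection_estimate(curve: DiscreteCurve, n_directions: int = 1000,
                           seed: int = 0) -> MCEstimate:
    """Estimate writhe and acn by crossing counting over random projections."""
    _require_points(curve, 5)
    if n_directions < 100:
        raise ValueError("need at least 100 directions")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_directions, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    signed = np.zeros(n_directions)
    unsigned = np.zeros(n_directions)
    for k, u in enumerate(dirs):
        crossings = projected_crossings(curve, u)
        signed[k] = sum(c[2] for c in crossings)
        unsigned[k] = len(crossings)
    return MCEstimate(
        float(signed.mean()),
        float(unsigned.mean()),
        float(signed.std(ddof=1) / math.sqrt(n_directions)),
        float(unsigned.std(ddof=1) / math.sqrt(n_directions)),
    )
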