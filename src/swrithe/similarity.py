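"""Writhe-profile similarity between smoothed backbones.

Two equal-length windows, one on each curve, are scored by the weighted
mean absolute difference of their subsection writhe values,

    S = 1/(w - 4) * sum_{m=4}^{w} |Wr1(i, i+m) - Wr2(l, l+m)| / (0.24 m),

normalized so a score of 0.05 means the profiles differ on average by
less than 5% of the typical empirically observed linear writhe growth
(gradient 0.12, doubled for opposite-sign profiles).  Subsection writhe
is undefined below a 6-point span, so the m = 4 term reuses the
shortest defined value (span 5); this keeps the printed 1/(w-4)
prefactor intact.

``compare_molecules`` scores all equal-length window pairs of at least
``min_len`` points, then greedily keeps the largest mutually similar
windows that are disjoint on both curves, reporting per-curve coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import gauss
from .gauss import Fingerprint, MIN_SPAN
from .skmt import SmoothedCurve

__all__ = [
    "window_score",
    "Match",
    "MatchSet",
    "compare_molecules",
    "similarity_curve",
    "sweep",
]

DEFAULT_S0 = 0.05
DEFAULT_MIN_LEN = 10
GROWTH_NORM = 0.24  # 2 x the empirical linear writhe gradient 0.12


def _as_fingerprint(obj) -> Fingerprint:
    if isinstance(obj, Fingerprint):
        return obj
    curve = obj.curve if isinstance(obj, SmoothedCurve) else obj
    return gauss.fingerprint(curve)


def window_score(fp1: Fingerprint, i: int, fp2: Fingerprint, l: int, w: int) -> float:
    """Similarity score of windows ``[i, i+w]`` and ``[l, l+w]`` (1-based)."""
    if w < MIN_SPAN:
        raise ValueError(f"window length must be at least {MIN_SPAN}")
    if i < 1 or i + w > fp1.n_points:
        raise ValueError(f"window [{i}, {i + w}] exceeds curve 1 ({fp1.n_points} points)")
    if l < 1 or l + w > fp2.n_points:
        raise ValueError(f"window [{l}, {l + w}] exceeds curve 2 ({fp2.n_points} points)")
    total = 0.0
    for m in range(4, w + 1):
        span = max(m, MIN_SPAN)
        total += abs(fp1.wr(i, i + span) - fp2.wr(l, l + span)) / (GROWTH_NORM * m)
    return total / (w - 4)


@dataclass(frozen=True)
class Match:
    range1: tuple[int, int]  # 1-based inclusive point range on curve 1
    range2: tuple[int, int]
    score: float

    @property
    def length(self) -> int:
        return self.range1[1] - self.range1[0]


@dataclass(frozen=True)
class MatchSet:
    matches: tuple[Match, ...]
    coverage1: float  # percent of curve-1 points inside matched ranges
    coverage2: float
    s0: float
    min_len: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "s0": self.s0,
                "min_len": self.min_len,
                "coverage1": round(self.coverage1, 6),
                "coverage2": round(self.coverage2, 6),
                "matches": [
                    {
                        "range1": list(m.range1),
                        "range2": list(m.range2),
                        "score": round(m.score, 6),
                    }
                    for m in self.matches
                ],
            }
        )


def _span_table(fp: Fingerprint) -> np.ndarray:
    """``V[a, m]`` = writhe of the window of span ``m`` starting at 0-based ``a``.

    The column ``m = 4`` holds the span-5 value (shortest defined);
    undefined entries are NaN.
    """
    n = fp.n_points
    V = np.full((n, n), np.nan)
    wr = fp._wr
    for a in range(n - MIN_SPAN):
        ms = np.arange(MIN_SPAN, n - a)
        V[a, ms] = wr[a, a + ms]
    if n > MIN_SPAN:
        V[:, 4] = V[:, MIN_SPAN]
    return V


def compare_molecules(c1, c2, s0: float = DEFAULT_S0,
                      min_len: int = DEFAULT_MIN_LEN) -> MatchSet:
    """Largest disjoint mutually similar windows between two smoothed curves."""
    fp1 = _as_fingerprint(c1)
    fp2 = _as_fingerprint(c2)
    n1, n2 = fp1.n_points, fp2.n_points
    if min(n1, n2) < min_len + 1:
        raise ValueError(
            f"curves must have at least {min_len + 1} points (got {n1}, {n2})"
        )
    V1 = _span_table(fp1)
    V2 = _span_table(fp2)
    max_w = min(n1, n2) - 1
    ms = np.arange(4, max_w + 1)
    weights = 1.0 / (GROWTH_NORM * ms)
    denom = np.arange(max_w + 1) - 4.0  # (w - 4) for index w

    cand_w, cand_s, cand_i, cand_l = [], [], [], []
    for a in range(n1 - min_len):
        # cumulative weighted |profile difference| over m for all l at once
        diff = np.abs(V1[a, 4 : max_w + 1][None, :] - V2[:, 4 : max_w + 1]) * weights
        cum = np.cumsum(diff, axis=1)  # column k -> w = k + 4
        ws = np.arange(min_len, max_w + 1)
        scores = cum[:, ws - 4] / denom[ws]
        ok = np.nonzero(scores < s0)
        if ok[0].size:
            cand_w.append(ws[ok[1]])
            cand_s.append(scores[ok])
            cand_i.append(np.full(ok[0].size, a + 1))
            cand_l.append(ok[0] + 1)

    if not cand_w:
        return MatchSet((), 0.0, 0.0, s0, min_len)

    w_arr = np.concatenate(cand_w)
    s_arr = np.concatenate(cand_s)
    i_arr = np.concatenate(cand_i)
    l_arr = np.concatenate(cand_l)
    order = np.lexsort((l_arr, i_arr, s_arr, -w_arr))

    chosen: list[Match] = []
    used1 = np.zeros(n1 + 2, dtype=bool)
    used2 = np.zeros(n2 + 2, dtype=bool)
    for k in order:
        i, l, w = int(i_arr[k]), int(l_arr[k]), int(w_arr[k])
        if used1[i : i + w + 1].any() or used2[l : l + w + 1].any():
            continue
        used1[i : i + w + 1] = True
        used2[l : l + w + 1] = True
        chosen.append(Match((i, i + w), (l, l + w), float(s_arr[k])))

    cov1 = 100.0 * used1[1 : n1 + 1].sum() / n1
    cov2 = 100.0 * used2[1 : n2 + 1].sum() / n2
    return MatchSet(tuple(chosen), float(cov1), float(cov2), s0, min_len)


def similarity_curve(c1, c2, s0_grid,
                     min_len: int = DEFAULT_MIN_LEN) -> list[tuple[float, float, float]]:
    """Coverage of both curves as a function of the tolerance ``s0``."""
    fp1 = _as_fingerprint(c1)
    fp2 = _as_fingerprint(c2)
    out = []
    for s0 in s0_grid:
        if not (0.0 < s0 < 1.0):
            raise ValueError("s0 grid values must lie in (0, 1)")
        ms = compare_molecules(fp1, fp2, s0=s0, min_len=min_len)
        out.append((float(s0), ms.coverage1, ms.coverage2))
    return out


def sweep(query, database, s0: float = DEFAULT_S0, min_coverage: float = 80.0,
          min_len: int = DEFAULT_MIN_LEN, one_sided: bool = False):
    """Compare a query against each database entry; keep high-coverage hits.

    By default both curves must reach ``min_coverage`` percent; with
    ``one_sided=True`` only the query's coverage is constrained.
    Returns ``(index, MatchSet)`` pairs.
    """
    fpq = _as_fingerprint(query)
    hits = []
    for idx, entry in enumerate(database):
        try:
            ms = compare_molecules(fpq, _as_fingerprint(entry), s0=s0, min_len=min_len)
        except ValueError:
            continue
        if ms.coverage1 >= min_coverage and (one_sided or ms.coverage2 >= min_coverage):
            hits.append((idx, ms))
    return hits
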