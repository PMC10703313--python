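"""Closed-form helix writhe and detection of super-helical subsections.

A stretch of a smoothed backbone whose cumulative writhe profile grows
linearly with consistent sign indicates large-scale coiling.  Detection
smooths the profile with LOWESS, scans every window of at least
``min_len`` points for a least-squares slope above ``min_gradient`` with
sign-consistent first differences, and reports the largest disjoint
windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import gauss
from .gauss import Fingerprint
from .skmt import SmoothedCurve

__all__ = [
    "helix_writhe_per_turn",
    "HelicalSection",
    "find_helical_sections",
    "gradient_census",
]

DEFAULT_MIN_LEN = 20
DEFAULT_MIN_GRADIENT = 0.05
DEFAULT_LOWESS_FRAC = 0.1


def helix_writhe_per_turn(pitch: float, radius: float) -> float:
    """Writhe accumulated per helical turn: ``1 - P / sqrt(P^2 + 4 pi^2 R^2)``."""
    if pitch < 0 or radius < 0:
        raise ValueError("pitch and radius must be non-negative")
    if pitch == 0 and radius == 0:
        raise ValueError("degenerate helix: pitch and radius both zero")
    return 1.0 - pitch / math.sqrt(pitch ** 2 + 4.0 * math.pi ** 2 * radius ** 2)


@dataclass(frozen=True)
class HelicalSection:
    """A detected super-helical window, in 1-based smoothed-point indices."""

    start: int
    end: int
    gradient: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _smoothed_profile(fp: Fingerprint, frac: float) -> tuple[np.ndarray, np.ndarray]:
    ns, wr = fp.profile()
    frac = min(1.0, max(frac, 5.0 / max(len(ns), 1)))
    sm = lowess(wr, ns.astype(float), frac=frac, return_sorted=True)
    return ns, sm[:, 1]


def find_helical_sections(fp: Fingerprint, min_len: int = DEFAULT_MIN_LEN,
                          min_gradient: float = DEFAULT_MIN_GRADIENT,
                          lowess_frac: float = DEFAULT_LOWESS_FRAC,
                          ) -> list[HelicalSection]:
    """Largest disjoint windows of consistent, steep linear writhe growth."""
    ns, y = _smoothed_profile(fp, lowess_frac)
    m = len(ns)
    if m < 2:
        return []
    x = ns.astype(float)

    # prefix sums for O(1) least-squares slopes over any window
    cx, cy = np.concatenate([[0.0], np.cumsum(x)]), np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])

    # prefix counts of strictly positive / negative first differences
    d = np.diff(y)
    pos = np.concatenate([[0], np.cumsum(d > 0)])
    neg = np.concatenate([[0], np.cumsum(d < 0)])

    candidates = []
    for a in range(m):
        for b in range(a + 1, m):
            if ns[b] - ns[a] < min_len:
                continue
            k = b - a + 1
            sx = cx[b + 1] - cx[a]
            sy = cy[b + 1] - cy[a]
            sxx = cxx[b + 1] - cxx[a]
            sxy = cxy[b + 1] - cxy[a]
            denom = k * sxx - sx * sx
            if denom <= 0:
                continue
            slope = (k * sxy - sx * sy) / denom
            if abs(slope) <= min_gradient:
                continue
            n_pos = pos[b] - pos[a]
            n_neg = neg[b] - neg[a]
            if n_pos and n_neg:
                continue  # winding direction changes inside the window
            candidates.append(HelicalSection(int(ns[a]), int(ns[b]), float(slope)))

    candidates.sort(key=lambda h: (-h.length, -abs(h.gradient), h.start))
    chosen: list[HelicalSection] = []
    for cand in candidates:
        if all(cand.end < c.start or cand.start > c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda h: h.start)
    return chosen


def gradient_census(curves, min_len: int = DEFAULT_MIN_LEN,
                    min_gradient: float = DEFAULT_MIN_GRADIENT,
                    lowess_frac: float = DEFAULT_LOWESS_FRAC) -> list[float]:
    """Gradient of the largest helical section of each curve, if any.

    Accepts :class:`SmoothedCurve` objects (or bare curves); curves with no
    qualifying section contribute nothing.  Gradients below the threshold
    are excluded by construction.
    """
    out = []
    for c in curves:
        curve = c.curve if isinstance(c, SmoothedCurve) else c
        if curve.n_points < gauss.MIN_SPAN + 1:
            continue
        sections = find_helical_sections(
            gauss.fingerprint(curve), min_len, min_gradient, lowess_frac
        )
        if sections:
            best = max(sections, key=lambda h: (h.length, abs(h.gradient)))
            out.append(best.gradient)
    return out
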