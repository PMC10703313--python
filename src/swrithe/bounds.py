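"""Entanglement bounds as functions of smoothed-backbone length.

``L`` is always the number of points of the smoothed curve.  The bounds
are the theoretical thick-knot writhe limit ``(1/4)(L/R)^{4/3}`` with the
empirical radius ``R = 2.7``, the empirical linear writhe bound ``0.12 L``,
and for the average crossing number the linear cap ``L``, the empirical
floor ``(L/7.5)^{1.6} - 3`` and the random-walk-style ``(3/16) L ln L``
growth.  The plausibility gate is the simple step function
``acn >= (L/7.5)^{1.6} - 3``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

from . import gauss
from .skmt import SmoothedCurve

__all__ = [
    "knot_bound",
    "linear_wr_bound",
    "acn_lower_bound",
    "acn_nlogn_bound",
    "BoundsReport",
    "assess",
]

DEFAULT_RADIUS = 2.7
LINEAR_WR_GRADIENT = 0.12
ACN_LOWER_SCALE = 7.5
ACN_LOWER_EXP = 1.6
ACN_LOWER_SHIFT = 3.0
ACN_NLOGN_COEF = 3.0 / 16.0


def knot_bound(L: float, R: float = DEFAULT_RADIUS) -> float:
    """Thick-knot writhe limit ``(1/4)(L/R)^{4/3}``."""
    if L <= 0 or R <= 0:
        raise ValueError("L and R must be positive")
    return 0.25 * (L / R) ** (4.0 / 3.0)


def linear_wr_bound(L: float) -> float:
    """Empirical linear writhe bound ``0.12 L``."""
    if L < 0:
        raise ValueError("L must be non-negative")
    return LINEAR_WR_GRADIENT * L


def acn_lower_bound(L: float) -> float:
    """Empirical acn floor ``(L/7.5)^{1.6} - 3`` (may be negative; unclamped)."""
    if L < 0:
        raise ValueError("L must be non-negative")
    return (L / ACN_LOWER_SCALE) ** ACN_LOWER_EXP - ACN_LOWER_SHIFT


def acn_nlogn_bound(L: float) -> float:
    """Random-walk-style growth ``(3/16) L ln L`` (natural log)."""
    if L <= 0:
        raise ValueError("L must be positive")
    return ACN_NLOGN_COEF * L * math.log(L)


@dataclass(frozen=True)
class BoundsReport:
    L: int
    wr_value: float
    acn_value: float
    knot_bound: float
    linear_wr_bound: float
    acn_upper: float
    acn_lower: float
    acn_nlogn: float
    within_knot: bool
    within_linear: bool
    plausible: bool

    def to_json(self) -> str:
        obj = asdict(self)
        return json.dumps(
            {k: (round(v, 6) if isinstance(v, float) else v) for k, v in obj.items()}
        )


def assess(smoothed: SmoothedCurve, R: float = DEFAULT_RADIUS) -> BoundsReport:
    """Whole-curve writhe/acn of a smoothed backbone against all bounds.

    The plausibility flag is the step-function gate used to penalize
    scattering-fit candidates whose acn falls below the empirical floor.
    """
    L = smoothed.skmt_length
    if L < 6:
        raise ValueError(f"smoothed curve too short for assessment (L={L} < 6)")
    wr = gauss.writhe(smoothed.curve)
    ac = gauss.acn(smoothed.curve)
    kb = knot_bound(L, R)
    lb = linear_wr_bound(L)
    floor = acn_lower_bound(L)
    return BoundsReport(
        L=L,
        wr_value=wr,
        acn_value=ac,
        knot_bound=kb,
        linear_wr_bound=lb,
        acn_upper=float(L),
        acn_lower=floor,
        acn_nlogn=acn_nlogn_bound(L),
        within_knot=abs(wr) <= kb,
        within_linear=abs(wr) <= lb,
        plausible=ac >= floor,
    )
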