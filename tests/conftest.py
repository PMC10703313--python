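import math

import numpy as np
import pytest

from swrithe.curves import DiscreteCurve, make_helix, make_mock_backbone, make_random_walk, make_trefoil
from swrithe.pdb_io import SSAssignment, pair
from swrithe import skmt as skmt_mod


@pytest.fixture(scope="session")
def helix():
    """Fine helix at the reference pitch/radius, 14 turns."""
    return make_helix(7.58, 5.98, 50, 14)


@pytest.fixture(scope="session")
def coarse_helix():
    """Coarse helix (7 points/turn) whose writhe gradient is near 0.12/point."""
    return make_helix(7.58, 5.98, 7, 8)


@pytest.fixture(scope="session")
def trefoil():
    return make_trefoil(200)


@pytest.fixture(scope="session")
def walk30():
    return make_random_walk(30, 3.8, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_rotation(rng):
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


@pytest.fixture(scope="session")
def threaded_backbone():
    """A linker threading past an edge of a later section.

    Straightening the linker to a single chord would flip the crossing it
    makes with the later section's long edge, so the smoothing must keep
    at least one interior linker point.
    """
    pts = np.array(
        [
            [0, 0, 0], [4, 0, 0], [8, 0, 0],        # E
            [10, 0, 4], [14, 0, 4], [16, 0, 0],     # C (threads the wall)
            [12, -5, -4], [12, 5, 6], [12, 5, 10],  # E (contains the wall edge)
        ],
        dtype=float,
    )
    return pair(DiscreteCurve(pts, "threaded"), SSAssignment("EEECCCEEE"))


def passage_curve(z_apex: float) -> DiscreteCurve:
    """Open loop plus a tail whose final edge passes a loop edge as z_apex moves.

    Between z_apex = -8.6 and -9.1 the tail edge sweeps through a loop
    edge (a strand passage), so the writhe jumps by ~2 across that range.
    """
    th = np.linspace(0, 2 * math.pi * 0.97, 24)
    loop = np.column_stack([3 * np.cos(th), 3 * np.sin(th), np.zeros_like(th)])
    tail = np.array([[4.0, 0.1, 3.0], [0.0, 0.1, z_apex], [-1.0, 0.5, z_apex]])
    return DiscreteCurve(np.vstack([loop, tail]))


def smooth_mock(sse_spec, seed):
    curve, ss = make_mock_backbone(sse_spec, seed=seed)
    return skmt_mod.skmt(pair(curve, ss))
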