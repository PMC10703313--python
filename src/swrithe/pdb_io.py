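"""PDB backbone extraction and secondary-structure handling.

Reads C-alpha backbones from PDB-format text (first model, one chain,
first alternate location), parses PSIPRED vertical ``.ss2`` files or plain
3-state strings, cleans spurious singleton SSE assignments and pairs
coordinates with labels into a validated :class:`LabeledBackbone`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .curves import DiscreteCurve

__all__ = [
    "SSAssignment",
    "LabeledBackbone",
    "read_ca_backbone",
    "read_ss_psipred",
    "ss_from_pdb_records",
    "clean_ss",
    "pair",
    "read_labeled_backbone",
    "write_ca_pdb",
]

# Consecutive C-alpha separations outside this range flag a chain break.
MIN_CA_SEP = 2.5
MAX_CA_SEP = 4.5

# DSSP-style 8-state to 3-state reduction.
_STATE_MAP = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def _to_three_state(raw: str) -> str:
    return "".join(_STATE_MAP.get(ch, "C") for ch in raw.upper())


@dataclass(frozen=True)
class SSAssignment:
    """Per-residue 3-state secondary structure labels over ``{H, E, C}``."""

    labels: str

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("empty secondary structure assignment")
        mapped = _to_three_state(self.labels)
        object.__setattr__(self, "labels", mapped)

    def __len__(self) -> int:
        return len(self.labels)

    @cached_property
    def sections(self) -> list[tuple[str, int, int]]:
        """Maximal runs as ``(label, start, end)``, 0-based inclusive."""
        secs = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                secs.append((self.labels[start], start, i - 1))
                start = i
        return secs


@dataclass(frozen=True)
class LabeledBackbone:
    """A C-alpha curve paired with a same-length secondary structure."""

    curve: DiscreteCurve
    ss: SSAssignment
    source: str = ""

    def __post_init__(self) -> None:
        if self.curve.n_points != len(self.ss):
            raise ValueError(
                f"backbone has {self.curve.n_points} residues but the "
                f"assignment covers {len(self.ss)}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _as_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if "\n" not in text and text.endswith((".pdb", ".ent", ".ss2", ".txt", ".xyz")):
        return Path(text).read_text()
    return text


def _first_altloc_ca(residue):
    atom = residue["CA"]
    if atom.is_disordered():
        children = sorted(atom.disordered_get_list(), key=lambda a: a.get_altloc())
        atom = children[0]
    return atom


def _ca_records(pdb_text: str, chain: str | None, model: int):
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise ValueError("no models found in PDB source")
    mdl = models[model]
    chains = {c.id: c for c in mdl}
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found; available chains: {sorted(chains)}"
        )
    coords, resids = [], []
    for res in chains[chain]:
        if res.id[0] != " " or "CA" not in res:
            continue
        coords.append(_first_altloc_ca(res).get_coord())
        resids.append((res.id[1], res.id[2].strip()))
    if not coords:
        raise ValueError(f"no C-alpha atoms found in chain {chain!r}")
    return np.asarray(coords, dtype=float), resids, chain


def read_ca_backbone(pdb_source, chain: str | None = None, model: int = 0,
                     label: str = "") -> DiscreteCurve:
    """C-alpha backbone of one chain of a PDB file.

    Uses the first model and the first alternate location; heteroatoms are
    excluded.  Edges whose C-alpha separation falls outside
    ``[2.5, 4.5]`` Angstrom are flagged as chain breaks (with a warning),
    never silently bridged.
    """
    coords, resids, chain = _ca_records(_as_text(pdb_source), chain, model)
    if coords.shape[0] < 2:
        raise ValueError(f"chain {chain!r} has fewer than 2 C-alpha atoms")
    seps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    breaks = frozenset(
        int(k) for k in np.nonzero((seps < MIN_CA_SEP) | (seps > MAX_CA_SEP))[0]
    )
    if breaks:
        warnings.warn(
            f"chain {chain!r}: {len(breaks)} chain break(s) flagged at edges "
            f"{sorted(breaks)}", stacklevel=2,
        )
    return DiscreteCurve(coords, label or f"chain {chain}", breaks)


def read_ss_psipred(ss2_source) -> SSAssignment:
    """Parse a PSIPRED vertical ``.ss2`` file (index, residue, state, 3 scores)."""
    text = _as_text(ss2_source)
    states = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 3:
            raise ValueError(f"malformed .ss2 line: {line!r}")
        states.append(fields[2])
    if not states:
        raise ValueError("no residue lines found in .ss2 source")
    return SSAssignment("".join(states))


def ss_from_pdb_records(pdb_source, chain: str | None = None,
                        model: int = 0) -> SSAssignment:
    """3-state assignment derived from PDB HELIX/SHEET records.

    A fallback when no PSIPRED file is available; residues inside HELIX
    records are labeled H, inside SHEET records E, all others C.
    """
    text = _as_text(pdb_source)
    _, resids, chain = _ca_records(text, chain, model)
    spans_h, spans_e = [], []
    for line in text.splitlines():
        line = line.ljust(40)
        rec = line[:6]
        if rec == "HELIX ":
            if line[19].strip() == chain and line[31].strip() == chain:
                spans_h.append((int(line[21:25]), int(line[33:37])))
        elif rec == "SHEET ":
            if line[21].strip() == chain and line[32].strip() == chain:
                spans_e.append((int(line[22:26]), int(line[33:37])))
    labels = []
    for seq, _icode in resids:
        lab = "C"
        for lo, hi in spans_h:
            if lo <= seq <= hi:
                lab = "H"
                break
        else:
            for lo, hi in spans_e:
                if lo <= seq <= hi:
                    lab = "E"
                    break
        labels.append(lab)
    return SSAssignment("".join(labels))


# ---------------------------------------------------------------------------
# cleaning and pairing
# ---------------------------------------------------------------------------


def clean_ss(ss: SSAssignment) -> SSAssignment:
    """Relabel singleton H/E runs flanked by linker (or chain ends) as C.

    A single pass suffices: relabeling to C only merges C runs, so the
    operation is idempotent.
    """
    labels = list(ss.labels)
    for lab, start, end in ss.sections:
        if lab == "C" or end != start:
            continue
        left_ok = start == 0 or labels[start - 1] == "C"
        right_ok = end == len(labels) - 1 or labels[end + 1] == "C"
        if left_ok and right_ok:
            labels[start] = "C"
    return SSAssignment("".join(labels))


def pair(curve: DiscreteCurve, ss: SSAssignment, source: str = "") -> LabeledBackbone:
    """Pair a backbone with its assignment; cleaning is applied automatically."""
    if curve.n_points != len(ss):
        raise ValueError(
            f"length mismatch: curve has {curve.n_points} points, "
            f"assignment has {len(ss)} labels"
        )
    return LabeledBackbone(curve, clean_ss(ss), source)


def read_labeled_backbone(pdb_source, chain: str | None = None, model: int = 0,
                          ss=None, source: str = "") -> LabeledBackbone:
    """One-stop reader: backbone plus secondary structure.

    ``ss`` may be an :class:`SSAssignment`, a path to a ``.ss2`` file, a
    plain state string, or ``None`` to fall back to the PDB's own
    HELIX/SHEET records.
    """
    text = _as_text(pdb_source)
    curve = read_ca_backbone(text, chain, model)
    if ss is None:
        assignment = ss_from_pdb_records(text, chain, model)
    elif isinstance(ss, SSAssignment):
        assignment = ss
    else:
        ss_text = _as_text(ss)
        if "\n" in ss_text.strip():
            assignment = read_ss_psipred(ss_text)
        else:
            assignment = SSAssignment(ss_text.strip())
    return pair(curve, assignment, source or curve.label)


def write_ca_pdb(curve: DiscreteCurve, chain: str = "A") -> str:
    """Minimal CA-only PDB text (pseudo-atoms), 3-decimal precision."""
    lines = []
    for i, (x, y, z) in enumerate(curve.points, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
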