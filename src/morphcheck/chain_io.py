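"""Backbone I/O: CA traces from PDB text, TM-align alignment blocks, JSON reports.

The analysis operates on alpha-carbon traces only, so the reader extracts one
point per residue that has a CA record.  Alignment records index positions
along the extracted CA trace (1-based), not author residue numbers; the
original residue labels are kept on the :class:`Chain` for reporting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import gemmi
import numpy as np

__all__ = [
    "Chain",
    "AlignmentRecord",
    "read_ca_coordinates",
    "parse_tmalign_output",
    "format_tmalign_output",
    "write_report",
    "read_report",
]


@dataclass
class Chain:
    """An ordered alpha-carbon (or smoothened) trace.

    points
        (n, 3) float array of coordinates in Ångström.
    residue_labels
        one identifier per point, in chain order.
    representation
        ``"alpha"`` for raw CA traces, ``"smooth"`` after smoothening.
    source_id
        free-text provenance tag.
    """

    points: np.ndarray
    residue_labels: List[str] = field(default_factory=list)
    representation: str = "alpha"
    source_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 3:
            raise ValueError("a chain needs at least 3 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValueError("consecutive chain points must be distinct")
        if not self.residue_labels:
            self.residue_labels = [str(i + 1) for i in range(len(self.points))]
        if len(self.residue_labels) != len(self.points):
            raise ValueError("one residue label per point required")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AlignmentRecord:
    """A residue alignment between two chains plus the rigid transform.

    ``pairs`` holds 1-based (index in chain 0, index in chain 1) tuples,
    strictly increasing in both coordinates.  ``weak_flags`` marks pairs that
    were "." (weakly aligned) columns; they are treated as aligned downstream.
    ``rotation``/``translation`` map chain-1 coordinates onto chain 0.
    """

    pairs: List[Tuple[int, int]]
    weak_flags: List[bool]
    len0: int
    len1: int
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    method: str = "external"

    def __post_init__(self):
        self.pairs = [(int(i), int(j)) for i, j in self.pairs]
        self.weak_flags = [bool(w) for w in self.weak_flags]
        if len(self.weak_flags) != len(self.pairs):
            raise ValueError("one weak flag per pair required")
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        prev = (0, 0)
        for (i, j) in self.pairs:
            if i <= prev[0] or j <= prev[1]:
                raise ValueError("alignment pairs must be strictly increasing")
            prev = (i, j)
        if self.pairs:
            if self.pairs[-1][0] > self.len0 or self.pairs[-1][1] > self.len1:
                raise ValueError("alignment index outside chain length")

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the stored rigid transform (rotation then translation)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


def read_ca_coordinates(pdb_text: str, chain_id: str, model_index: int = 0) -> Chain:
    """Extract one CA point per residue of ``chain_id`` from PDB-format text.

    Alternate locations are resolved by highest occupancy, ties by first
    occurrence.  Residues lacking a CA record are skipped (their labels do
    not appear in ``residue_labels``).
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("no models in PDB text")
    if model_index >= len(structure):
        raise ValueError(
            f"model index {model_index} out of range ({len(structure)} models)"
        )
    model = structure[model_index]
    names = [ch.name for ch in model]
    if chain_id not in names:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {sorted(set(names))}"
        )
    points = []
    labels = []
    for ch in model:
        if ch.name != chain_id:
            continue
        for residue in ch:
            best = None
            for atom in residue:
                if atom.name != "CA":
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is not None:
                points.append([best.pos.x, best.pos.y, best.pos.z])
                labels.append(str(residue.seqid.num))
    if len(points) < 3:
        raise ValueError(
            f"chain {chain_id!r} has only {len(points)} CA records (need >= 3)"
        )
    return Chain(
        points=np.array(points, dtype=float),
        residue_labels=labels,
        representation="alpha",
        source_id=chain_id,
    )


_MARKER_CHARS = set(": .")


def parse_tmalign_output(text: str) -> AlignmentRecord:
    """Parse the standard TM-align three-line alignment block.

    The block is sequence 0, a marker line of ``:`` (aligned), ``.`` (weakly
    aligned) and spaces, then sequence 1.  ``:`` and ``.`` columns become
    pairs; ``.`` sets the weak flag.  Header lines around the block are
    ignored.
    """
    lines = text.splitlines()
    block = None
    for k in range(1, len(lines) - 1):
        line = lines[k]
        if not line.strip():
            continue
        if set(line) <= _MARKER_CHARS and (":" in line or "." in line):
            seq0 = lines[k - 1]
            seq1 = lines[k + 1]
            if seq0.strip() and seq1.strip():
                block = (seq0, line, seq1)
                break
    if block is None:
        raise ValueError("no TM-align marker line (':'/'.') found")
    seq0, marker, seq1 = block
    n = max(len(seq0), len(seq1), len(marker))
    if len(seq0.rstrip()) != len(seq1.rstrip()):
        # tolerate trailing whitespace only
        if len(seq0.strip("\r ")) != len(seq1.strip("\r ")):
            raise ValueError("alignment sequence lines have unequal lengths")
    seq0 = seq0.ljust(n)
    seq1 = seq1.ljust(n)
    marker = marker.ljust(n)

    pairs = []
    weak = []
    i0 = 0
    i1 = 0
    for col in range(n):
        c0, cm, c1 = seq0[col], marker[col], seq1[col]
        gap0 = c0 in "- "
        gap1 = c1 in "- "
        if not gap0:
            i0 += 1
        if not gap1:
            i1 += 1
        if cm in ":.":
            if gap0 or gap1:
                raise ValueError(f"aligned column {col} touches a gap")
            pairs.append((i0, i1))
            weak.append(cm == ".")
    return AlignmentRecord(
        pairs=pairs, weak_flags=weak, len0=i0, len1=i1, method="tm_align"
    )


def format_tmalign_output(record: AlignmentRecord) -> str:
    """Render an AlignmentRecord as a TM-align three-line block.

    Residue identities are not stored on the record, so sequences are
    rendered with 'A' placeholders; parse(format(x)) recovers the pairs,
    weak flags and chain lengths.
    """
    cols0, colsm, cols1 = [], [], []
    i0, i1 = 1, 1
    for (p0, p1), w in zip(record.pairs, record.weak_flags):
        while i0 < p0 and i1 < p1:
            cols0.append("A")
            colsm.append(" ")
            cols1.append("A")
            i0 += 1
            i1 += 1
        while i0 < p0:
            cols0.append("A")
            colsm.append(" ")
            cols1.append("-")
            i0 += 1
        while i1 < p1:
            cols0.append("-")
            colsm.append(" ")
            cols1.append("A")
            i1 += 1
        cols0.append("A")
        colsm.append("." if w else ":")
        cols1.append("A")
        i0 += 1
        i1 += 1
    while i0 <= record.len0 and i1 <= record.len1:
        cols0.append("A")
        colsm.append(" ")
        cols1.append("A")
        i0 += 1
        i1 += 1
    while i0 <= record.len0:
        cols0.append("A")
        colsm.append(" ")
        cols1.append("-")
        i0 += 1
    while i1 <= record.len1:
        cols0.append("-")
        colsm.append(" ")
        cols1.append("A")
        i1 += 1
    return "\n".join(("".join(cols0), "".join(colsm), "".join(cols1))) + "\n"


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(report, path: str) -> None:
    """Serialize a MorphReport (or any dataclass tree) to JSON at ``path``."""
    with open(path, "w") as fh:
        json.dump(_to_jsonable(report), fh, indent=1, allow_nan=True)


def read_report(path: str) -> dict:
    """Load a report written by :func:`write_report` back into nested dicts."""
    with open(path) as fh:
        return json.load(fh)
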