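"""Protein distance matrices from multiple sequence alignments.

Implements the observed-difference (p) distance restricted to mutually
ungapped columns and its Jukes-Cantor correction for the 20-letter amino-acid
alphabet,

    d = -b * ln(1 - p / b),    b = 19/20,

the role EMBOSS ``distmat`` plays in alignment-based pipelines.  Distances at
or beyond the correction's domain edge (p >= b, or no comparable columns at
all) are reported as a finite saturation cap so downstream sums and argmins
stay well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "JC_B",
    "SATURATION_CAP",
    "p_distance",
    "jukes_cantor",
    "distance_matrix",
]

#: Jukes-Cantor alphabet constant for proteins: (k-1)/k with k = 20 states.
JC_B = 19.0 / 20.0

#: Finite stand-in for a saturated (undefined or unbounded) corrected distance.
SATURATION_CAP = 10.0

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """A protein multiple sequence alignment.

    ``rows`` is an ordered list of ``(seq_id, genome_id, aligned_residues)``;
    every row has the same length and the alphabet is amino acids plus ``-``.
    """

    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        rows = tuple(tuple(r) for r in self.rows)
        object.__setattr__(self, "rows", rows)
        if rows:
            n = len(rows[0][2])
            for sid, _, res in rows:
                if len(res) != n:
                    raise ValueError(
                        f"row {sid!r} has length {len(res)}, expected {n}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][2]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def row(self, seq_id: str) -> str:
        for sid, _, res in self.rows:
            if sid == seq_id:
                return res
        raise KeyError(seq_id)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal.

    ``saturated[i, j]`` marks entries that hit the saturation cap rather than
    being genuine corrected distances.
    """

    ids: list[str]
    d: np.ndarray
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.saturated is None:
            self.saturated = np.zeros_like(self.d, dtype=bool)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])

    def to_distmat_text(self) -> str:
        """Lower-triangular text rendering, for inspection."""
        lines = []
        for i, sid in enumerate(self.ids):
            vals = "\t".join(f"{self.d[i, j]:.4f}" for j in range(i))
            lines.append(f"{sid}\t{vals}" if vals else sid)
        return "\n".join(lines) + "\n"


def p_distance(a: str, b: str) -> float:
    """Observed fraction of differing residues over mutually ungapped columns.

    Columns where either row carries a gap are excluded.  ``X`` is treated as
    mismatching everything, itself included.  With zero comparable columns the
    distance is undefined and 1.0 (the saturation sentinel on the p scale) is
    returned.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned rows differ in length: {len(a)} vs {len(b)}")
    compared = 0
    mismatches = 0
    for ca, cb in zip(a, b):
        if ca == GAP or cb == GAP:
            continue
        compared += 1
        if ca != cb or ca == "X":
            mismatches += 1
    if compared == 0:
        return 1.0
    return mismatches / compared


def jukes_cantor(p: float, b: float = JC_B, cap: float = SATURATION_CAP) -> float:
    """Jukes-Cantor corrected distance d = -b ln(1 - p/b).

    Strictly increasing in p on [0, b); p >= b returns the finite saturation
    cap rather than raising, so degenerate pairs stay comparable.
    """
    if p < 0:
        raise ValueError(f"p-distance {p} is negative")
    if p >= b:
        return cap
    return min(-b * math.log1p(-p / b), cap)


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise Jukes-Cantor corrected distances for every row pair."""
    if len(aln.rows) < 2:
        raise ValueError("distance matrix needs at least 2 aligned rows")
    n = len(aln.rows)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln.rows[i][2], aln.rows[j][2])
            dij = jukes_cantor(p)
            d[i, j] = d[j, i] = dij
            if dij >= SATURATION_CAP:
                sat[i, j] = sat[j, i] = True
    return DistanceMatrix(ids=[r[0] for r in aln.rows], d=d, saturated=sat)
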