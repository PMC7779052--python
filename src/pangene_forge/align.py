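"""Minimal progressive multiple alignment for desk-scale runs.

Production pipelines feed externally computed alignments (MAFFT output read
as aligned FASTA) into the consensus step; this module provides a
self-contained fallback so the whole pipeline runs without external binaries:
progressive profile-profile Needleman-Wunsch (Gotoh affine gaps) under
BLOSUM62, joining sequences in input order.  It is adequate for the closely
related sequences found inside within-species clusters; it is not a general
replacement for a real aligner.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .distances import Alignment
from .io_formats import ProteinSequence

__all__ = ["progressive_align", "align_pair"]

_BLOSUM = substitution_matrices.load("BLOSUM62")
GAP_OPEN = -11.0
GAP_EXTEND = -1.0
_GAP_VS_RESIDUE = -4.0  # scoring a profile-internal gap against a residue


def _score_cols(col_a: str, col_b: str) -> float:
    """Mean pairwise substitution score between two profile columns."""
    total = 0.0
    n = 0
    for ca in col_a:
        for cb in col_b:
            if ca == "-" and cb == "-":
                s = 0.0
            elif ca == "-" or cb == "-":
                s = _GAP_VS_RESIDUE
            else:
                try:
                    s = _BLOSUM[ca, cb]
                except (KeyError, IndexError):
                    s = _BLOSUM["X", "X"]
            total += s
            n += 1
    return total / n


def _align_profiles(prof_a: list[str], prof_b: list[str]) -> tuple[list[str], list[str]]:
    """Gotoh global alignment of two profiles; returns gap-padded profiles."""
    la, lb = len(prof_a[0]), len(prof_b[0])
    cols_a = ["".join(r[i] for r in prof_a) for i in range(la)]
    cols_b = ["".join(r[j] for r in prof_b) for j in range(lb)]
    sub = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            sub[i, j] = _score_cols(cols_a[i], cols_b[j])

    neg = -1e30
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND)

    # traceback; ties prefer match, then consuming A, for determinism
    out_a: list[list[str]] = [[] for _ in prof_a]
    out_b: list[list[str]] = [[] for _ in prof_b]
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            nstate = int(np.argmax(prev))
            for k, r in enumerate(prof_a):
                out_a[k].append(r[i - 1])
            for k, r in enumerate(prof_b):
                out_b[k].append(r[j - 1])
            i, j, state = i - 1, j - 1, nstate
        elif state == 1 or j == 0:
            nstate = 0 if M[i - 1, j] + GAP_OPEN >= X[i - 1, j] + GAP_EXTEND else 1
            for k, r in enumerate(prof_a):
                out_a[k].append(r[i - 1])
            for k in range(len(prof_b)):
                out_b[k].append("-")
            i, state = i - 1, nstate
        else:
            nstate = 0 if M[i, j - 1] + GAP_OPEN >= Y[i, j - 1] + GAP_EXTEND else 2
            for k in range(len(prof_a)):
                out_a[k].append("-")
            for k, r in enumerate(prof_b):
                out_b[k].append(r[j - 1])
            j, state = j - 1, nstate
    return (
        ["".join(reversed(r)) for r in out_a],
        ["".join(reversed(r)) for r in out_b],
    )


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment of two unaligned sequences."""
    ra, rb = _align_profiles([a], [b])
    return ra[0], rb[0]


def progressive_align(seqs: Sequence[ProteinSequence]) -> Alignment:
    """Progressively align sequences in input order into one Alignment."""
    if not seqs:
        raise ValueError("nothing to align")
    profile = [seqs[0].residues]
    for s in seqs[1:]:
        profile, new = _align_profiles(profile, [s.residues])
        profile.append(new[0])
    return Alignment(
        rows=tuple(
            (s.seq_id, s.genome_id, row) for s, row in zip(seqs, profile)
        )
    )
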