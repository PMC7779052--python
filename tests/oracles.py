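"""Independent brute-force reference implementations used only by tests.

These are deliberately written as plainly as possible (explicit loops, no
shared helpers with the package) so that agreement with the package is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def consensus_brute(rows, genome_ranking):
    """rows: list of (seq_id, genome_id, aligned_string). Majority consensus
    with gap-majority column drops and BUSCO-rank tie-breaking."""
    n_cols = len(rows[0][2])
    out = []
    for c in range(n_cols):
        column = [(g, r[c]) for _, g, r in rows]
        residues = [res for _, res in column if res != "-"]
        gaps = len(column) - len(residues)
        if gaps > len(residues):
            continue
        counts = Counter(residues)
        top = max(counts.values())
        tied = sorted(res for res, k in counts.items() if k == top)
        if len(tied) == 1:
            out.append(tied[0])
            continue
        picked = None
        for g in genome_ranking:
            for gg, res in column:
                if gg == g and res in tied:
                    picked = res
                    break
            if picked is not None:
                break
        out.append(picked)
    return "".join(out)


def representative_brute(members, dm_ids, dm):
    """members: list of (seq_id, genome_id). Per genome with >=2 members,
    exhaustive candidate sums of distances to all other-genome members."""
    idx = {s: i for i, s in enumerate(dm_ids)}
    genomes = sorted({g for _, g in members})
    chosen = {}
    for g in genomes:
        mine = sorted(s for s, gg in members if gg == g)
        if len(mine) == 1:
            chosen[g] = mine[0]
            continue
        others = [s for s, gg in members if gg != g]
        best = None
        for cand in mine:
            total = 0.0
            for o in others:
                total += dm[idx[cand]][idx[o]]
            if best is None or total < best[0] - 1e-12:
                best = (total, cand)
        chosen[g] = best[1]
    return chosen


def genotype_representative_brute(members, dm_ids, dm):
    idx = {s: i for i, s in enumerate(dm_ids)}
    ids = sorted(s for s, _ in members)
    best = None
    for cand in ids:
        others = [s for s in ids if s != cand]
        mean = sum(dm[idx[cand]][idx[o]] for o in others) / len(others)
        if best is None or mean < best[0] - 1e-12:
            best = (mean, cand)
    return best[1]


def jc_brute(p):
    b = 0.95
    if p >= b:
        return 10.0
    return min(-b * math.log(1.0 - p / b), 10.0)


def p_distance_brute(a, b):
    comp = mism = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comp += 1
        if x != y or x == "X":
            mism += 1
    return 1.0 if comp == 0 else mism / comp


def mcl_reference(nodes, edge_weights, inflation, max_iter=300):
    """A second, independently written Markov clustering.

    Dense matrix, explicit normalization loops, and the classic attractor
    interpretation: attractors are nodes with positive diagonal mass; each
    attractor's row defines a cluster; overlapping clusters are merged.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    A = [[0.0] * n for _ in range(n)]
    for (u, v), w in edge_weights.items():
        A[pos[u]][pos[v]] = w
        A[pos[v]][pos[u]] = w
    for i in range(n):
        mx = max(A[i])
        A[i][i] = mx if mx > 0 else 1.0
    M = np.array(A)
    M = M / M.sum(axis=0)
    for _ in range(max_iter):
        prev = M.copy()
        M = M @ M
        M = M ** inflation
        M[M < 1e-8] = 0.0
        s = M.sum(axis=0)
        s[s == 0] = 1.0
        M = M / s
        if np.abs(M - prev).max() < 1e-6:
            break
    # attractor interpretation
    clusters = []
    for i in range(n):
        if M[i][i] > 1e-6:
            members = {nodes[j] for j in range(n) if M[i][j] > 1e-6}
            members.add(nodes[i])
            clusters.append(members)
    # nodes not reached by any attractor row: singletons
    covered = set().union(*clusters) if clusters else set()
    for v in nodes:
        if v not in covered:
            clusters.append({v})
    # merge overlapping clusters
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return sorted((frozenset(c) for c in clusters), key=lambda c: (-len(c), min(c)))


def specificity_brute(families, annotations):
    """families: {fid: set of members}; annotations: list of
    (seq_id, signature_id).  Double loop over families x signatures."""
    out = {}
    sigs = sorted({sig for _, sig in annotations})
    for fid, members in families.items():
        for sig in sigs:
            inside = {s for s, g in annotations if g == sig and s in members}
            if not inside:
                continue
            outside = False
            for other_fid, other_members in families.items():
                if other_fid == fid:
                    continue
                for s, g in annotations:
                    if g == sig and s in other_members:
                        outside = True
            out[(fid, sig)] = {
                "coverage": 100.0 * len(inside) / len(members),
                "specific": not outside,
            }
    return out


def best_hit_brute(hit_rows):
    """hit_rows: (query, subject, evalue, bitscore). Best per query."""
    best = {}
    for q, s, ev, bs in hit_rows:
        if q not in best:
            best[q] = (s, ev, bs)
        else:
            cs, cev, cbs = best[q]
            if (bs > cbs or (bs == cbs and ev < cev)
                    or (bs == cbs and ev == cev and s < cs)):
                best[q] = (s, ev, bs)
    return {q: v[0] for q, v in best.items()}


def species_overlap_brute(children_leaf_species):
    """children_leaf_species: list of species sets, one per child subtree."""
    for i in range(len(children_leaf_species)):
        for j in range(i + 1, len(children_leaf_species)):
            if children_leaf_species[i] & children_leaf_species[j]:
                return "duplication"
    return "speciation"
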