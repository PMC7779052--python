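"""Pangene construction: one representative/consensus unit per species gene.

A species with several sequenced genomes carries each gene in up to one copy
per assembly.  Within-species sequence clusters are collapsed into *pangenes*:

* single-copy clusters (one sequence per genome) are aligned and reduced to a
  majority-rule consensus, ties broken by the genome with the best BUSCO
  scores;
* multi-copy clusters first select, per genome, the member with the smallest
  summed distance to all members of the *other* genomes, then run the
  single-copy procedure on those representatives;
* genotype-specific clusters (paralogs confined to one genome) keep the member
  with the lowest average distance to the rest, verbatim;
* singletons are kept only when external similarity hits reach at least two
  other species, otherwise they are excluded from the pangene set.

Pangenes are named ``<species>_pan_p<NNNNNN>`` and classified core (every
genome of the species contributes a representative) or dispensable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

from .distances import Alignment, DistanceMatrix, distance_matrix
from .io_formats import GenomeMeta, Hit, ProteinSequence

__all__ = [
    "ClusterKind",
    "Compartment",
    "SequenceCluster",
    "Pangene",
    "PangeneStats",
    "classify_cluster",
    "rank_genomes",
    "select_representative",
    "select_genotype_representative",
    "build_consensus",
    "rescue_singletons",
    "assign_ids",
    "classify_compartment",
    "build_pangenes",
    "PANGENE_ID_RE",
]

logger = logging.getLogger(__name__)

PANGENE_ID_RE = re.compile(r"^[a-z]{5}_pan_p[0-9]{6}$")

GAP = "-"


class ClusterKind(str, Enum):
    SINGLE_COPY = "single_copy"
    MULTI_COPY = "multi_copy"
    GENOTYPE_SPECIFIC = "genotype_specific"
    SINGLETON = "singleton"


class Compartment(str, Enum):
    CORE = "core"
    DISPENSABLE = "dispensable"


@dataclass
class SequenceCluster:
    """A within-species cluster of homologous sequences."""

    cluster_id: str
    species_code: str
    members: list[ProteinSequence]
    kind: ClusterKind

    @property
    def genomes(self) -> set[str]:
        return {m.genome_id for m in self.members}


@dataclass
class Pangene:
    """A species-level gene unit: consensus or representative sequence plus
    the member sequences that back it (role ``rep`` entered the consensus,
    role ``p`` are the remaining paralogs/participants)."""

    pangene_id: str
    species_code: str
    sequence: str
    members: list[tuple[str, str, str]]  # (seq_id, genome_id, role)
    compartment: Compartment
    source_kind: ClusterKind
    cluster_id: str = ""

    @property
    def rep_genomes(self) -> set[str]:
        return {g for _, g, role in self.members if role == "rep"}

    @property
    def member_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.members]


@dataclass
class PangeneStats:
    species_code: str
    n_pangenes: int
    n_sequences: int
    n_singletons_excluded: int
    pct_singletons_excluded: float
    n_core: int
    n_dispensable: int


def classify_cluster(
    members: Sequence[ProteinSequence], n_genomes_in_species: int
) -> ClusterKind:
    """Type a within-species cluster by member count and genome multiplicity.

    Precedence: singleton (one member), genotype-specific (one genome),
    multi-copy (some genome holds >= 2 members), else single-copy.
    """
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return ClusterKind.SINGLETON
    genomes = [m.genome_id for m in members]
    if len(set(genomes)) == 1:
        return ClusterKind.GENOTYPE_SPECIFIC
    if any(genomes.count(g) >= 2 for g in set(genomes)):
        return ClusterKind.MULTI_COPY
    return ClusterKind.SINGLE_COPY


def rank_genomes(metas: Sequence[GenomeMeta]) -> list[str]:
    """Order genomes by annotation quality: BUSCO complete descending, then
    fragmented descending, then missing ascending, then genome id."""
    for m in metas:
        if m.busco_complete is None:  # dataclass enforces floats; belt and braces
            raise ValueError(f"missing BUSCO scores for {m.genome_id}")
    return [
        m.genome_id
        for m in sorted(
            metas,
            key=lambda m: (
                -m.busco_complete,
                -m.busco_fragmented,
                m.busco_missing,
                m.genome_id,
            ),
        )
    ]


def select_representative(
    cluster: SequenceCluster, dm: DistanceMatrix
) -> dict[str, str]:
    """Pick one representative per genome in a multi-copy cluster.

    For every genome with several members, each candidate's score is its
    summed distance to all members of the *other* genomes; the argmin wins,
    ties going to the lexicographically smallest seq id.  Single-member
    genomes keep their sequence.  Saturated distances participate at the cap.
    """
    by_genome: dict[str, list[ProteinSequence]] = {}
    for m in cluster.members:
        by_genome.setdefault(m.genome_id, []).append(m)
    idx = {sid: i for i, sid in enumerate(dm.ids)}
    chosen: dict[str, str] = {}
    for genome, members in sorted(by_genome.items()):
        if len(members) == 1:
            chosen[genome] = members[0].seq_id
            continue
        others = [m for m in cluster.members if m.genome_id != genome]
        best_id, best_sum = None, None
        for cand in sorted(members, key=lambda m: m.seq_id):
            s = sum(dm.d[idx[cand.seq_id], idx[o.seq_id]] for o in others)
            if best_sum is None or s < best_sum:
                best_id, best_sum = cand.seq_id, s
        chosen[genome] = best_id  # type: ignore[assignment]
    return chosen


def select_genotype_representative(
    cluster: SequenceCluster, dm: DistanceMatrix
) -> str:
    """Member with the lowest average distance to all other members; ties to
    the smallest seq id.  The winner becomes the pangene sequence verbatim."""
    if len(cluster.members) < 2:
        raise ValueError("genotype-specific cluster needs >= 2 members")
    idx = {sid: i for i, sid in enumerate(dm.ids)}
    best_id, best_mean = None, None
    for m in sorted(cluster.members, key=lambda m: m.seq_id):
        others = [o for o in cluster.members if o.seq_id != m.seq_id]
        mean = sum(dm.d[idx[m.seq_id], idx[o.seq_id]] for o in others) / len(others)
        if best_mean is None or mean < best_mean:
            best_id, best_mean = m.seq_id, mean
    return best_id  # type: ignore[return-value]


def build_consensus(aln: Alignment, genome_ranking: Sequence[str]) -> str:
    """Majority-rule consensus over a one-row-per-genome alignment.

    Per column: if gaps outnumber residues the column is dropped; otherwise
    the modal residue wins; a modal tie goes to the residue held, at that
    column, by the highest-ranked genome among those holding a tied residue.
    The result never contains gaps.
    """
    rank = {g: i for i, g in enumerate(genome_ranking)}
    out: list[str] = []
    for col in range(aln.n_columns):
        residues = [(r[2][col], r[1]) for r in aln.rows]
        non_gap = [(res, g) for res, g in residues if res != GAP]
        n_gaps = len(residues) - len(non_gap)
        if n_gaps > len(non_gap):
            continue
        counts: dict[str, int] = {}
        for res, _ in non_gap:
            counts[res] = counts.get(res, 0) + 1
        top = max(counts.values())
        tied = {res for res, c in counts.items() if c == top}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            # best-ranked genome whose residue at this column is in the tie
            winner = min(
                (
                    (rank.get(g, len(rank)), g, res)
                    for res, g in non_gap
                    if res in tied
                ),
            )
            out.append(winner[2])
    if not out:
        raise ValueError("degenerate consensus: every column was dropped")
    return "".join(out)


def rescue_singletons(
    singletons: Sequence[ProteinSequence],
    hits: Iterable[Hit],
    seq2species: Mapping[str, str],
    min_species: int = 2,
) -> tuple[list[ProteinSequence], list[ProteinSequence]]:
    """Split singletons into (kept, excluded) by cross-species hit support.

    A singleton survives when its hits reach at least ``min_species`` distinct
    species other than its own; hit counts within one species do not help.
    """
    support: dict[str, set[str]] = {s.seq_id: set() for s in singletons}
    own_species = {
        s.seq_id: seq2species.get(s.seq_id, "") for s in singletons
    }
    for h in hits:
        if h.query_id in support and not h.is_self:
            sp = seq2species.get(h.subject_id)
            if sp and sp != own_species[h.query_id]:
                support[h.query_id].add(sp)
    kept = [s for s in singletons if len(support[s.seq_id]) >= min_species]
    excluded = [s for s in singletons if len(support[s.seq_id]) < min_species]
    return kept, excluded


def assign_ids(pangenes: Sequence[Pangene], species_code: str) -> list[Pangene]:
    """Set ``<species>_pan_p<NNNNNN>`` ids in order, counting from 000001."""
    if len(pangenes) > 999_999:
        raise ValueError("more than 999999 pangenes; id space exhausted")
    out = []
    for i, pg in enumerate(pangenes, start=1):
        pg.pangene_id = f"{species_code}_pan_p{i:06d}"
        out.append(pg)
    return out


def classify_compartment(
    pangene: Pangene, all_genome_ids_of_species: Iterable[str]
) -> Compartment:
    """Core iff every genome of the species contributes a representative."""
    needed = set(all_genome_ids_of_species)
    return (
        Compartment.CORE
        if pangene.rep_genomes >= needed
        else Compartment.DISPENSABLE
    )


def _subset_alignment(aln: Alignment, keep_ids: set[str]) -> Alignment:
    """Restrict an alignment to some rows, dropping columns gapped in all of
    them (the consensus gap-majority rule handles the rest)."""
    rows = [r for r in aln.rows if r[0] in keep_ids]
    keep_cols = [
        c for c in range(aln.n_columns) if any(r[2][c] != GAP for r in rows)
    ]
    return Alignment(
        rows=tuple(
            (sid, gid, "".join(res[c] for c in keep_cols)) for sid, gid, res in rows
        )
    )


def build_pangenes(
    clusters: Sequence[SequenceCluster],
    metas: Sequence[GenomeMeta],
    aligner: Callable[[Sequence[ProteinSequence]], Alignment],
    hits: Iterable[Hit] = (),
    seq2species: Mapping[str, str] | None = None,
    precomputed_alignments: Mapping[str, Alignment] | None = None,
) -> tuple[list[Pangene], PangeneStats, list[ProteinSequence]]:
    """Run the full per-species pangene construction.

    ``clusters`` must all belong to one species and partition its sequences.
    ``hits`` and ``seq2species`` feed the singleton rescue test (hits of
    singletons against other species' proteomes).  ``precomputed_alignments``
    maps cluster_id to an externally produced alignment, bypassing ``aligner``.

    Returns the pangene list (ids assigned, compartments set), summary stats,
    and the excluded singletons.
    """
    if not clusters:
        raise ValueError("no clusters")
    species = clusters[0].species_code
    if any(c.species_code != species for c in clusters):
        raise ValueError("clusters span multiple species")
    species_metas = [m for m in metas if m.species_code == species]
    ranking = rank_genomes(species_metas)
    all_genomes = {m.genome_id for m in species_metas}
    seq2species = seq2species or {}
    precomputed = precomputed_alignments or {}

    def get_alignment(cluster_id: str, seqs: list[ProteinSequence]) -> Alignment:
        if cluster_id in precomputed:
            return precomputed[cluster_id]
        return aligner(seqs)

    pangenes: list[Pangene] = []
    excluded: list[ProteinSequence] = []
    n_sequences = sum(len(c.members) for c in clusters)

    hits = list(hits)
    # rescue all singletons in one pass
    singleton_clusters = [c for c in clusters if c.kind == ClusterKind.SINGLETON]
    singleton_seqs = [c.members[0] for c in singleton_clusters]
    kept_singletons, excluded_singletons = rescue_singletons(
        singleton_seqs, hits, seq2species
    )
    kept_ids = {s.seq_id for s in kept_singletons}
    excluded.extend(excluded_singletons)

    for cluster in sorted(clusters, key=lambda c: c.cluster_id):
        try:
            if cluster.kind == ClusterKind.SINGLETON:
                m = cluster.members[0]
                if m.seq_id not in kept_ids:
                    continue
                pangenes.append(
                    Pangene(
                        pangene_id="",
                        species_code=species,
                        sequence=m.residues,
                        members=[(m.seq_id, m.genome_id, "rep")],
                        compartment=Compartment.DISPENSABLE,
                        source_kind=cluster.kind,
                        cluster_id=cluster.cluster_id,
                    )
                )
            elif cluster.kind == ClusterKind.GENOTYPE_SPECIFIC:
                aln = get_alignment(cluster.cluster_id, cluster.members)
                dm = distance_matrix(aln)
                rep = select_genotype_representative(cluster, dm)
                seq = next(m.residues for m in cluster.members if m.seq_id == rep)
                pangenes.append(
                    Pangene(
                        pangene_id="",
                        species_code=species,
                        sequence=seq,
                        members=[
                            (m.seq_id, m.genome_id, "rep" if m.seq_id == rep else "p")
                            for m in cluster.members
                        ],
                        compartment=Compartment.DISPENSABLE,
                        source_kind=cluster.kind,
                        cluster_id=cluster.cluster_id,
                    )
                )
            elif cluster.kind == ClusterKind.MULTI_COPY:
                aln = get_alignment(cluster.cluster_id, cluster.members)
                dm = distance_matrix(aln)
                rep_by_genome = select_representative(cluster, dm)
                rep_ids = set(rep_by_genome.values())
                rep_aln = _subset_alignment(aln, rep_ids)
                seq = build_consensus(rep_aln, ranking)
                pangenes.append(
                    Pangene(
                        pangene_id="",
                        species_code=species,
                        sequence=seq,
                        members=[
                            (
                                m.seq_id,
                                m.genome_id,
                                "rep" if m.seq_id in rep_ids else "p",
                            )
                            for m in cluster.members
                        ],
                        compartment=Compartment.DISPENSABLE,
                        source_kind=cluster.kind,
                        cluster_id=cluster.cluster_id,
                    )
                )
            else:  # single copy
                aln = get_alignment(cluster.cluster_id, cluster.members)
                seq = build_consensus(aln, ranking)
                pangenes.append(
                    Pangene(
                        pangene_id="",
                        species_code=species,
                        sequence=seq,
                        members=[
                            (m.seq_id, m.genome_id, "rep") for m in cluster.members
                        ],
                        compartment=Compartment.DISPENSABLE,
                        source_kind=cluster.kind,
                        cluster_id=cluster.cluster_id,
                    )
                )
        except ValueError as exc:
            logger.error("cluster %s failed: %s", cluster.cluster_id, exc)
            continue

    pangenes = assign_ids(pangenes, species)
    for pg in pangenes:
        pg.compartment = classify_compartment(pg, all_genomes)

    n_excl = len(excluded)
    stats = PangeneStats(
        species_code=species,
        n_pangenes=len(pangenes),
        n_sequences=n_sequences,
        n_singletons_excluded=n_excl,
        pct_singletons_excluded=(100.0 * n_excl / n_sequences) if n_sequences else 0.0,
        n_core=sum(1 for p in pangenes if p.compartment == Compartment.CORE),
        n_dispensable=sum(
            1 for p in pangenes if p.compartment == Compartment.DISPENSABLE
        ),
    )
    return pangenes, stats, excluded
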