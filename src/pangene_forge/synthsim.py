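"""Synthetic multi-genome pangenome datasets with planted ground truth.

Emulates the input structure of a comparative-pangenomics study — several
plant species, several genome assemblies per species, gene families shared
across species, within-genome duplications, presence/absence variation (PAV)
and sequence divergence — together with the truth tables needed to score
every downstream step.  All randomness flows from one seed; identical
configurations produce byte-identical outputs.

The model is deliberately simple: a random ancestral protein per family,
substitution-only divergence (no indels, so family members stay equal
length), per-genome family loss at ``pav_rate``, and duplicate copies at
``dup_rate`` with extra divergence.  Hits are synthesized from true family
co-membership with e-values decreasing in sequence identity, keeping tests
hermetic; real-engine integration stays possible by exporting the FASTA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .io_formats import (
    GenomeMeta,
    Hit,
    ProteinSequence,
    write_busco_table,
    write_fasta,
    write_hits,
    write_membership_tsv,
)

__all__ = ["SimConfig", "TruthTables", "SyntheticDataset", "simulate", "emit_toy_worked_example"]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Extra divergence applied to duplicated copies, as a multiple of sub_rate.
DUPLICATE_DIVERGENCE_FACTOR = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic pangenome."""

    n_species: int = 3
    genomes_per_species: int = 3
    n_families: int = 50
    pav_rate: float = 0.2
    dup_rate: float = 0.1
    sub_rate: float = 0.02
    seq_len: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pav_rate", "dup_rate", "sub_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        for name in ("n_species", "genomes_per_species", "n_families", "seq_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class TruthTables:
    """Planted ground truth aligned with the emitted sequence ids."""

    family_of: dict[str, str]  # seq_id -> family id
    compartment: dict[tuple[str, str], str]  # (family, species) -> core|dispensable
    ortholog_pairs: set[tuple[str, str]]  # sorted id pairs, reference genomes
    in_paralog_pairs: set[tuple[str, str]]
    representative_classes: dict[tuple[str, str], set[str]]  # (family, species) -> ids
    reference_genome: dict[str, str]  # species -> genome id used for homology truth


@dataclass
class SyntheticDataset:
    config: SimConfig
    sequences: dict[str, list[ProteinSequence]]  # genome_id -> sequences
    metas: list[GenomeMeta]
    hits: list[Hit]
    truth: TruthTables

    @property
    def all_sequences(self) -> list[ProteinSequence]:
        return [s for g in sorted(self.sequences) for s in self.sequences[g]]

    def seq2species(self) -> dict[str, str]:
        sp = {m.genome_id: m.species_code for m in self.metas}
        return {s.seq_id: sp[s.genome_id] for s in self.all_sequences}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the dataset in the pipeline's input formats; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for gid in sorted(self.sequences):
            p = outdir / f"{gid}.faa"
            write_fasta(self.sequences[gid], p)
            paths[f"fasta:{gid}"] = p
        paths["busco"] = outdir / "busco.tsv"
        write_busco_table(self.metas, paths["busco"])
        paths["hits"] = outdir / "hits.tsv"
        write_hits(self.hits, paths["hits"])
        paths["truth_families"] = outdir / "truth_families.tsv"
        write_membership_tsv(
            sorted((fam, "", sid) for sid, fam in self.truth.family_of.items()),
            paths["truth_families"],
            header=("cluster_id", "cluster_name", "seq_id"),
        )
        paths["truth_compartments"] = outdir / "truth_compartments.tsv"
        write_membership_tsv(
            sorted(
                (fam, sp, comp) for (fam, sp), comp in self.truth.compartment.items()
            ),
            paths["truth_compartments"],
            header=("family_id", "species_code", "compartment"),
        )
        paths["truth_homologs"] = outdir / "truth_homologs.tsv"
        rows = [(a, b, "ortholog") for a, b in sorted(self.truth.ortholog_pairs)]
        rows += [(a, b, "in_paralog") for a, b in sorted(self.truth.in_paralog_pairs)]
        write_membership_tsv(
            rows, paths["truth_homologs"], header=("id_a", "id_b", "relation")
        )
        return paths


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` (to a different residue)."""
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    for i in np.flatnonzero(mask):
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def _species_codes(n: int) -> list[str]:
    if n > 26 * 26:
        raise ValueError("too many species")
    out = []
    for i in range(n):
        out.append("sp" + chr(97 + i // 26) + chr(97 + i % 26) * 2)
    return out


def _identity(a: str, b: str) -> float:
    same = sum(x == y for x, y in zip(a, b))
    return 100.0 * same / max(len(a), len(b))


def simulate(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset for one configuration.

    Per family: an ancestral random sequence diverges once per species, then
    once per genome, at ``sub_rate`` per site.  Each genome copy is deleted
    with probability ``pav_rate`` (families losing every copy everywhere are
    dropped from truth and FASTA alike) and duplicated with probability
    ``dup_rate``, the duplicate receiving extra divergence.  Hits are emitted
    in both directions for every within-family sequence pair.
    """
    rng = np.random.default_rng(cfg.seed)
    species = _species_codes(cfg.n_species)
    genomes = {
        sp: [f"{sp}_g{j + 1}" for j in range(cfg.genomes_per_species)]
        for sp in species
    }

    # BUSCO metadata: complete uniform in [85,100] to exercise the ranking
    metas: list[GenomeMeta] = []
    for sp in species:
        for gid in genomes[sp]:
            complete = float(rng.uniform(85.0, 100.0))
            fragmented = float(rng.uniform(0.0, min(5.0, 100.0 - complete)))
            missing = max(0.0, 100.0 - complete - fragmented)
            metas.append(
                GenomeMeta(
                    genome_id=gid,
                    species_code=sp,
                    busco_complete=round(complete, 2),
                    busco_fragmented=round(fragmented, 2),
                    busco_missing=round(missing, 2),
                )
            )

    sequences: dict[str, list[ProteinSequence]] = {
        gid: [] for sp in species for gid in genomes[sp]
    }
    family_of: dict[str, str] = {}
    compartment: dict[tuple[str, str], str] = {}
    rep_classes: dict[tuple[str, str], set[str]] = {}
    seq_strings: dict[str, str] = {}
    members_by_family: dict[str, list[str]] = {}
    dup_of: dict[str, str] = {}  # duplicate seq_id -> source seq_id

    for f in range(cfg.n_families):
        fam_id = f"FAM{f + 1:04d}"
        ancestral = rng.choice(AMINO_ACIDS, size=cfg.seq_len)
        fam_members: list[str] = []
        presence: dict[str, list[str]] = {sp: [] for sp in species}
        for sp in species:
            sp_seq = _mutate(rng, ancestral, cfg.sub_rate)
            for gid in genomes[sp]:
                g_seq = _mutate(rng, sp_seq, cfg.sub_rate)
                deleted = rng.random() < cfg.pav_rate
                duplicated = rng.random() < cfg.dup_rate
                if deleted:
                    continue
                sid = f"{gid}_f{f + 1:04d}"
                sequences[gid].append(
                    ProteinSequence(sid, gid, "".join(g_seq))
                )
                seq_strings[sid] = "".join(g_seq)
                family_of[sid] = fam_id
                fam_members.append(sid)
                presence[sp].append(gid)
                rep_classes.setdefault((fam_id, sp), set()).add(sid)
                if duplicated:
                    d_seq = _mutate(
                        rng, g_seq, cfg.sub_rate * DUPLICATE_DIVERGENCE_FACTOR
                    )
                    did = f"{sid}d1"
                    sequences[gid].append(
                        ProteinSequence(did, gid, "".join(d_seq))
                    )
                    seq_strings[did] = "".join(d_seq)
                    family_of[did] = fam_id
                    fam_members.append(did)
                    rep_classes[(fam_id, sp)].add(did)
                    dup_of[did] = sid
        if not fam_members:
            continue  # family extinct everywhere: dropped consistently
        members_by_family[fam_id] = fam_members
        for sp in species:
            if presence[sp]:
                compartment[(fam_id, sp)] = (
                    "core"
                    if len(set(presence[sp])) == len(genomes[sp])
                    else "dispensable"
                )

    # homology truth over one reference genome per species: the BUSCO-best,
    # matching the pipeline's choice of which assembly feeds the gene trees
    by_gid = {m.genome_id: m for m in metas}
    reference_genome = {
        sp: min(
            genomes[sp],
            key=lambda g: (
                -by_gid[g].busco_complete,
                -by_gid[g].busco_fragmented,
                by_gid[g].busco_missing,
                g,
            ),
        )
        for sp in species
    }
    ref_gids = set(reference_genome.values())
    ortho: set[tuple[str, str]] = set()
    inpara: set[tuple[str, str]] = set()
    gid_of = {sid: sid.rsplit("_f", 1)[0] for sid in family_of}
    for fam_id, members in members_by_family.items():
        ref_members = [m for m in members if gid_of[m] in ref_gids]
        for a, b in itertools.combinations(sorted(ref_members), 2):
            if gid_of[a] == gid_of[b]:
                inpara.add((a, b))
            else:
                ortho.add((a, b))

    # hits from true co-membership, e-value decreasing in identity
    hits: list[Hit] = []
    for fam_id, members in members_by_family.items():
        for a, b in itertools.permutations(sorted(members), 2):
            ident = _identity(seq_strings[a], seq_strings[b])
            evalue = 10.0 ** (-min(200.0, ident * 1.8))
            bitscore = round(2.0 * cfg.seq_len * ident / 100.0, 1)
            hits.append(Hit(a, b, round(ident, 2), evalue, bitscore))

    truth = TruthTables(
        family_of=family_of,
        compartment=compartment,
        ortholog_pairs=ortho,
        in_paralog_pairs=inpara,
        representative_classes=rep_classes,
        reference_genome=reference_genome,
    )
    return SyntheticDataset(
        config=cfg, sequences=sequences, metas=metas, hits=hits, truth=truth
    )


def emit_toy_worked_example(seed: int = 42) -> SyntheticDataset:
    """A fixed small dataset: one species, three genomes, five sequences in
    one family, with one genome contributing two copies (a multi-copy
    cluster).  Sequence content is synthetic; the structure is what matters.
    """
    cfg = SimConfig(
        n_species=1,
        genomes_per_species=3,
        n_families=1,
        pav_rate=0.0,
        dup_rate=0.0,
        sub_rate=0.03,
        seq_len=60,
        seed=seed,
    )
    ds = simulate(cfg)
    # add duplicated copies in two genomes -> 5 members over 3 genomes
    rng = np.random.default_rng(seed + 1)
    gids = sorted(ds.sequences)
    sp = ds.metas[0].species_code
    for gid in (gids[0], gids[2]):
        src = ds.sequences[gid][0]
        dup_res = "".join(
            _mutate(rng, np.array(list(src.residues)), cfg.sub_rate * 2)
        )
        dup = ProteinSequence(src.seq_id + "d1", gid, dup_res)
        ds.sequences[gid].append(dup)
        fam = ds.truth.family_of[src.seq_id]
        ds.truth.family_of[dup.seq_id] = fam
        ds.truth.representative_classes[(fam, sp)].add(dup.seq_id)
        others = [s for s in ds.all_sequences if s.seq_id != dup.seq_id]
        for o in others:
            ident = _identity(dup.residues, o.residues)
            ev = 10.0 ** (-min(200.0, ident * 1.8))
            bs = round(2.0 * cfg.seq_len * ident / 100.0, 1)
            ds.hits.append(Hit(dup.seq_id, o.seq_id, round(ident, 2), ev, bs))
            ds.hits.append(Hit(o.seq_id, dup.seq_id, round(ident, 2), ev, bs))
    return ds
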