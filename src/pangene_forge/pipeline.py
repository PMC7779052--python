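"""End-to-end pipeline: QC -> pangenes -> families -> naming -> homology.

Driven by a declarative YAML/dict configuration; every stage writes its
outputs under one run directory and records them, with content hashes and a
parameter snapshot, in ``manifest.json``.  Reruns with identical inputs and
configuration produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import families as fam_mod
from . import homology as hom_mod
from . import pangene as pan_mod
from .align import progressive_align
from .distances import distance_matrix
from .io_formats import (
    GenomeMeta,
    Hit,
    ProteinSequence,
    read_busco_table,
    read_fasta,
    read_hits,
    read_interproscan_tsv,
    read_membership_tsv,
    write_fasta,
    write_membership_tsv,
)

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "name_transfer": 0.51,
    "auto_name_coverage": 51.0,
    "singleton_rescue_min_species": 2,
    "inflations": [1.2, 2.0, 3.0, 5.0],
    "within_species_inflation": 2.0,
    "evalue_weight_cap": 200.0,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``fasta`` maps genome_id to its protein FASTA path; the genome ids must
    match the BUSCO metadata table.  Optional inputs (InterProScan TSV,
    previous-release membership) switch their stages on.
    """

    busco: Path
    fasta: dict[str, Path]
    hits: Path
    cds: dict[str, Path] = field(default_factory=dict)
    interpro: Path | None = None
    old_membership: Path | None = None
    thresholds: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")

        def p(x: str) -> Path:
            q = Path(x)
            return q if q.is_absolute() else base / q

        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(d.get("thresholds", {}))
        cfg = cls(
            busco=p(d["busco"]),
            fasta={gid: p(path) for gid, path in d["fasta"].items()},
            hits=p(d["hits"]),
            cds={gid: p(path) for gid, path in d.get("cds", {}).items()},
            interpro=p(d["interpro"]) if d.get("interpro") else None,
            old_membership=p(d["old_membership"]) if d.get("old_membership") else None,
            thresholds=thresholds,
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), base=path.parent)

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [self.busco, self.hits, *self.fasta.values(),
                      *self.cds.values(),
                      *( [self.interpro] if self.interpro else [] ),
                      *( [self.old_membership] if self.old_membership else [] )]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError("missing input file(s): " + ", ".join(missing))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _within_species_clusters(
    seqs: list[ProteinSequence],
    hits: list[Hit],
    species: str,
    inflation: float,
    n_genomes: int,
) -> list[pan_mod.SequenceCluster]:
    ids = {s.seq_id for s in seqs}
    within = [h for h in hits if h.query_id in ids and h.subject_id in ids]
    graph = fam_mod.build_graph(within)
    # sequences with no within-species hits are isolated singleton nodes
    node_set = set(graph.nodes) | ids
    graph = fam_mod.SimilarityGraph(nodes=sorted(node_set), edges=graph.edges)
    partition = fam_mod.mcl_cluster(graph, inflation)
    by_id = {s.seq_id: s for s in seqs}
    clusters = []
    for i, members in enumerate(
        sorted(partition, key=lambda c: min(c)), start=1
    ):
        mem = [by_id[m] for m in sorted(members)]
        clusters.append(
            pan_mod.SequenceCluster(
                cluster_id=f"{species}_c{i:05d}",
                species_code=species,
                members=mem,
                kind=pan_mod.classify_cluster(mem, n_genomes),
            )
        )
    return clusters


def _aggregate_pangene_hits(
    hits: list[Hit], seq2pangene: Mapping[str, str]
) -> list[Hit]:
    """Lift sequence-level hits to pangene level: per directed pangene pair
    keep the minimum e-value / maximum bitscore over member-pair hits."""
    best: dict[tuple[str, str], tuple[float, float, float]] = {}
    for h in hits:
        pq = seq2pangene.get(h.query_id)
        ps = seq2pangene.get(h.subject_id)
        if pq is None or ps is None or pq == ps:
            continue
        cur = best.get((pq, ps))
        cand = (h.evalue, -h.bitscore, h.pct_identity)
        if cur is None or cand < cur:
            best[(pq, ps)] = cand
    return [
        Hit(q, s, ident, ev, -negbs)
        for (q, s), (ev, negbs, ident) in sorted(best.items())
    ]


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": config.thresholds,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }
        manifest["stages"].setdefault(stage, []).append(name)

    try:
        metas = read_busco_table(config.busco)
        seqs_by_genome = {
            gid: read_fasta(path, genome_id=gid)
            for gid, path in sorted(config.fasta.items())
        }
        hits = list(read_hits(config.hits))
        species_of_genome = {m.genome_id: m.species_code for m in metas}
        seq2species = {
            s.seq_id: species_of_genome[gid]
            for gid, seqs in seqs_by_genome.items()
            for s in seqs
        }
        manifest["stages"]["load"] = {
            "n_genomes": len(seqs_by_genome),
            "n_sequences": sum(len(v) for v in seqs_by_genome.values()),
            "n_hits": len(hits),
        }
    except Exception:
        _write_manifest(manifest, outdir, failed_stage="load")
        raise

    # ---- QC (optional: needs CDS inputs) --------------------------------
    try:
        if config.cds:
            from .io_formats import check_dataset

            qc_rows = []
            for gid in sorted(config.cds):
                cds_seqs = read_fasta(config.cds[gid], genome_id=gid)
                report = check_dataset(
                    cds_seqs, seqs_by_genome.get(gid, []), genome_id=gid
                )
                qc_rows.append(
                    (
                        gid,
                        report.n_cds,
                        report.n_proteins,
                        report.n_locus_mismatches,
                        str(report.passed).lower(),
                    )
                )
            qc_path = outdir / "qc.tsv"
            write_membership_tsv(
                qc_rows,
                qc_path,
                header=("genome_id", "n_cds", "n_proteins", "n_locus_mismatches", "passed"),
            )
            record("qc", "qc_report", qc_path)
    except Exception:
        _write_manifest(manifest, outdir, failed_stage="qc")
        raise

    # ---- pangenes per species -------------------------------------------
    species_list = sorted({m.species_code for m in metas})
    seq2pangene: dict[str, str] = {}
    pangene_seqs: list[ProteinSequence] = []
    pangene_species: dict[str, str] = {}
    all_pangenes: list[pan_mod.Pangene] = []
    stats_rows = []
    excluded_rows = []
    try:
        for sp in species_list:
            genome_ids = sorted(
                m.genome_id for m in metas if m.species_code == sp
            )
            seqs = [s for g in genome_ids for s in seqs_by_genome.get(g, [])]
            clusters = _within_species_clusters(
                seqs,
                hits,
                sp,
                config.thresholds["within_species_inflation"],
                len(genome_ids),
            )
            pangenes, stats, excluded = pan_mod.build_pangenes(
                clusters,
                metas,
                progressive_align,
                hits=hits,
                seq2species=seq2species,
            )
            all_pangenes.extend(pangenes)
            excluded_rows.extend(
                (s.seq_id, s.genome_id, sp) for s in excluded
            )
            stats_rows.append(
                (
                    sp,
                    stats.n_pangenes,
                    stats.n_sequences,
                    stats.n_singletons_excluded,
                    f"{stats.pct_singletons_excluded:.2f}",
                    stats.n_core,
                    stats.n_dispensable,
                )
            )
            for pg in pangenes:
                pangene_species[pg.pangene_id] = sp
                pangene_seqs.append(
                    ProteinSequence(pg.pangene_id, sp, pg.sequence)
                )
                for sid, _, _ in pg.members:
                    seq2pangene[sid] = pg.pangene_id
        fasta_path = outdir / "pangenes.faa"
        write_fasta(pangene_seqs, fasta_path)
        record("pangenes", "pangene_fasta", fasta_path)
        mem_path = outdir / "pangene_members.tsv"
        write_membership_tsv(
            [
                (pg.pangene_id, sid, gid, role, pg.compartment.value)
                for pg in all_pangenes
                for sid, gid, role in pg.members
            ],
            mem_path,
            header=("pangene_id", "seq_id", "genome_id", "role", "compartment"),
        )
        record("pangenes", "pangene_members", mem_path)
        excl_path = outdir / "excluded_singletons.tsv"
        write_membership_tsv(
            excluded_rows,
            excl_path,
            header=("seq_id", "genome_id", "species_code"),
        )
        record("pangenes", "excluded_singletons", excl_path)
        stats_path = outdir / "pangene_stats.tsv"
        write_membership_tsv(
            stats_rows,
            stats_path,
            header=(
                "species_code",
                "n_pangenes",
                "n_sequences",
                "n_singletons_excluded",
                "pct_singletons_excluded",
                "n_core",
                "n_dispensable",
            ),
        )
        record("pangenes", "pangene_stats", stats_path)
    except Exception:
        _write_manifest(manifest, outdir, failed_stage="pangenes")
        raise

    # ---- cross-species families -----------------------------------------
    try:
        pg_hits = _aggregate_pangene_hits(hits, seq2pangene)
        graph = fam_mod.build_graph(
            pg_hits, evalue_cap=config.thresholds["evalue_weight_cap"]
        )
        node_set = set(graph.nodes) | {p.pangene_id for p in all_pangenes}
        graph = fam_mod.SimilarityGraph(nodes=sorted(node_set), edges=graph.edges)
        inflations = config.thresholds["inflations"]
        level_map = {i + 1: infl for i, infl in enumerate(inflations)}
        partitions = fam_mod.cluster_levels(graph, level_map)
        families_by_level = {
            level: fam_mod.make_families(part, level)
            for level, part in partitions.items()
        }
        fam_path = outdir / "families.tsv"
        write_membership_tsv(
            [
                (f.family_id, level, m)
                for level, fams in sorted(families_by_level.items())
                for f in fams
                for m in sorted(f.members)
            ],
            fam_path,
            header=("family_id", "level", "member_id"),
        )
        record("families", "families", fam_path)
    except Exception:
        _write_manifest(manifest, outdir, failed_stage="families")
        raise

    # ---- naming ----------------------------------------------------------
    try:
        if config.interpro:
            annotations = read_interproscan_tsv(config.interpro)
            # lift sequence-level annotations to pangene level
            lifted = []
            seen = set()
            for a in annotations:
                target = seq2pangene.get(a.seq_id, a.seq_id)
                key = (target, a.signature_id)
                if key in seen:
                    continue
                seen.add(key)
                lifted.append(
                    type(a)(
                        seq_id=target,
                        signature_id=a.signature_id,
                        signature_name=a.signature_name,
                        entry_type=a.entry_type,
                    )
                )
            naming_rows = []
            for level, fams in sorted(families_by_level.items()):
                if config.old_membership:
                    rows = read_membership_tsv(config.old_membership)
                    old: dict[str, set[str]] = {}
                    old_names: dict[str, str] = {}
                    for cid, cname, sid in rows:
                        old.setdefault(cid, set()).add(sid)
                        if cname:
                            old_names[cid] = cname
                    shared = frozenset().union(*old.values()) if old else frozenset()
                    fam_mod.transfer_names(
                        fams,
                        {k: frozenset(v) for k, v in old.items()},
                        old_names,
                        shared,
                        threshold=config.thresholds["name_transfer"],
                    )
                fam_mod.auto_name(
                    fams,
                    lifted,
                    min_coverage=config.thresholds["auto_name_coverage"],
                )
                naming_rows.extend(
                    (f.family_id, level, f.name or "", f.name_source.value)
                    for f in fams
                )
            naming_path = outdir / "family_names.tsv"
            write_membership_tsv(
                naming_rows,
                naming_path,
                header=("family_id", "level", "name", "name_source"),
            )
            record("naming", "family_names", naming_path)
    except Exception:
        _write_manifest(manifest, outdir, failed_stage="naming")
        raise

    # ---- homology --------------------------------------------------------
    try:
        homolog_rows = []
        # RBH between all genome pairs
        genome_of_seq = {
            s.seq_id: gid for gid, seqs in seqs_by_genome.items() for s in seqs
        }
        by_pair: dict[tuple[str, str], list[Hit]] = {}
        for h in hits:
            gq, gs = genome_of_seq.get(h.query_id), genome_of_seq.get(h.subject_id)
            if gq is None or gs is None or gq == gs:
                continue
            by_pair.setdefault((gq, gs), []).append(h)
        n_rbh = 0
        for ga, gb in sorted(by_pair):
            if ga >= gb:
                continue
            pairs = hom_mod.rbh(by_pair.get((ga, gb), []), by_pair.get((gb, ga), []))
            n_rbh += len(pairs)
            homolog_rows.extend(
                (p.id_a, p.id_b, p.relation.value, "rbh", "") for p in sorted(
                    pairs, key=lambda p: (p.id_a, p.id_b)
                )
            )
        # tree-based homologs per level-1 family over reference genomes
        ranking_by_sp = {
            sp: pan_mod.rank_genomes([m for m in metas if m.species_code == sp])
            for sp in species_list
        }
        reference = {sp: ranking_by_sp[sp][0] for sp in species_list}
        ref_gids = set(reference.values())
        members_of_pangene = {
            pg.pangene_id: pg.members for pg in all_pangenes
        }
        seq_by_id = {
            s.seq_id: s for seqs in seqs_by_genome.values() for s in seqs
        }
        n_tree_pairs = 0
        for famly in families_by_level.get(1, []):
            leaves: list[ProteinSequence] = []
            leaf_species: dict[str, str] = {}
            for member in sorted(famly.members):
                for sid, gid, _ in members_of_pangene.get(member, []):
                    if gid in ref_gids and sid in seq_by_id:
                        leaves.append(seq_by_id[sid])
                        leaf_species[sid] = species_of_genome[gid]
            if len(leaves) < 2:
                continue
            if len(leaves) == 2:
                tree = hom_mod.TreeNode(
                    children=[
                        hom_mod.TreeNode(name=s.seq_id, species=leaf_species[s.seq_id])
                        for s in leaves
                    ]
                )
                hom_mod.label_events(tree)
            else:
                aln = progressive_align(leaves)
                dm = distance_matrix(aln)
                nj = hom_mod.neighbor_joining(dm)
                for lf in nj.leaves():
                    lf.species = leaf_species[lf.name]
                tree = hom_mod.root_tree(nj)
            pairs = hom_mod.extract_homologs(tree)
            n_tree_pairs += len(pairs)
            homolog_rows.extend(
                (
                    p.id_a,
                    p.id_b,
                    p.relation.value,
                    "tree,method=species_overlap",
                    famly.family_id,
                )
                for p in sorted(pairs, key=lambda p: (p.id_a, p.id_b))
            )
        hom_path = outdir / "homologs.tsv"
        write_membership_tsv(
            homolog_rows,
            hom_path,
            header=("id_a", "id_b", "relation", "source", "family_id"),
        )
        record("homology", "homologs", hom_path)
        manifest["stages"]["homology_counts"] = {
            "n_rbh": n_rbh,
            "n_tree_pairs": n_tree_pairs,
        }
    except Exception:
        _write_manifest(manifest, outdir, failed_stage="homology")
        raise

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path, failed_stage: str | None = None) -> None:
    if failed_stage:
        manifest["failed_stage"] = failed_stage
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
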