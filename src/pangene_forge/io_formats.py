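"""Readers and writers for the formats the pipeline exchanges, plus dataset QC.

Formats handled: protein/CDS FASTA (via Biopython), aligned FASTA with ``-``
gaps, BLAST tabular (outfmt-6, 12 columns), InterProScan TSV, Newick gene
trees, previous-release membership TSV, and the internal TSV tables the
pipeline emits.  Also houses the dataset quality check (CDS/protein count and
locus-tag consistency) and longest-isoform filtering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinSequence",
    "GenomeMeta",
    "Hit",
    "HitList",
    "QcReport",
    "InterProAnnotation",
    "DEFAULT_LOCUS_PATTERN",
    "read_fasta",
    "write_fasta",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "read_hits",
    "write_hits",
    "read_busco_table",
    "write_busco_table",
    "read_interproscan_tsv",
    "read_gff3_mrna_parents",
    "read_newick",
    "read_membership_tsv",
    "write_membership_tsv",
    "check_dataset",
    "filter_longest_isoform",
    "locus_of",
]

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")
_SPECIES_CODE_RE = re.compile(r"^[a-z]{5}$")

#: Strips a trailing isoform suffix: ``.1``, ``-RA``, ``_T01`` and the like.
DEFAULT_LOCUS_PATTERN = r"^(.*?)(?:\.\d+|-R[A-Z]|_T\d+)$"


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence tied to its genome of origin.

    ``locus_id`` is the isoform-stripped gene identifier; it defaults to the
    full ``seq_id`` when no isoform suffix is recognized.
    """

    seq_id: str
    genome_id: str
    residues: str
    locus_id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        if "-" in self.residues:
            raise ValueError(f"gap character in sequence {self.seq_id!r}")
        if not self.locus_id:
            object.__setattr__(self, "locus_id", self.seq_id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomeMeta:
    """Genome assembly metadata: species code and BUSCO completeness scores.

    The three BUSCO percentages rank annotation quality; the ranking drives
    consensus tie-breaking (complete desc, fragmented desc, missing asc).
    """

    genome_id: str
    species_code: str
    busco_complete: float
    busco_fragmented: float
    busco_missing: float

    def __post_init__(self) -> None:
        if not _SPECIES_CODE_RE.match(self.species_code):
            raise ValueError(
                f"species code {self.species_code!r} must be 5 lowercase letters"
            )
        for name in ("busco_complete", "busco_fragmented", "busco_missing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0,100] for {self.genome_id}")


@dataclass(frozen=True)
class Hit:
    """One row of a BLAST-tabular similarity search."""

    query_id: str
    subject_id: str
    pct_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}->{self.subject_id}")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


class HitList(list):
    """A list of :class:`Hit` that remembers how many malformed rows were skipped."""

    def __init__(self, hits: Iterable[Hit] = (), n_skipped: int = 0) -> None:
        super().__init__(hits)
        self.n_skipped = n_skipped


@dataclass(frozen=True)
class QcReport:
    """Outcome of the CDS-vs-protein dataset consistency check for one genome."""

    genome_id: str
    n_cds: int
    n_proteins: int
    n_locus_mismatches: int
    n_isoforms_removed: int = 0

    @property
    def passed(self) -> bool:
        return self.n_cds == self.n_proteins and self.n_locus_mismatches == 0


@dataclass(frozen=True)
class InterProAnnotation:
    """One (sequence, InterPro signature) assignment."""

    seq_id: str
    signature_id: str
    signature_name: str
    entry_type: str  # "family", "domain", ...


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, genome_id: str = "") -> list[ProteinSequence]:
    """Read a protein FASTA file into :class:`ProteinSequence` records.

    Residues are uppercased and a single terminal ``*`` (stop codon) is
    stripped.  Duplicate ids within the file, empty sequences and internal
    ``*`` characters (translation artifacts) are hard errors.
    """
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        if "*" in residues:
            raise ValueError(f"internal stop codon in {rec.id!r}")
        if not residues:
            raise ValueError(f"empty sequence {rec.id!r} in {path}")
        records.append(
            ProteinSequence(seq_id=rec.id, genome_id=genome_id, residues=residues)
        )
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.seq_id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA (gap character ``-``); returns (id, row) pairs."""
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if rows:
        n = len(rows[0][1])
        for rid, row in rows:
            if len(row) != n:
                raise ValueError(f"ragged alignment: row {rid!r} length {len(row)} != {n}")
    return rows


def write_aligned_fasta(rows: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in rows:
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)


def read_hits(path: str | Path) -> HitList:
    """Parse a 12-column BLAST tabular file in row order.

    Columns 1, 2, 3, 11, 12 are query, subject, %identity, e-value, bitscore.
    Rows with fewer than 12 columns are skipped and counted on the returned
    list's ``n_skipped`` attribute.
    """
    hits: list[Hit] = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                n_skipped += 1
                continue
            hits.append(
                Hit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
    return HitList(hits, n_skipped=n_skipped)


def write_hits(hits: Iterable[Hit], path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular; unused columns are zero-filled."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}"
                f"\t0\t0\t0\t0\t0\t0\t0\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Metadata / annotation tables


def read_busco_table(path: str | Path) -> list[GenomeMeta]:
    """Read the genome metadata TSV: genome_id, species_code, complete,
    fragmented, missing.  A header line starting with ``genome_id`` is skipped."""
    metas: list[GenomeMeta] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("genome_id"):
                continue
            cols = line.split("\t")
            metas.append(
                GenomeMeta(
                    genome_id=cols[0],
                    species_code=cols[1],
                    busco_complete=float(cols[2]),
                    busco_fragmented=float(cols[3]),
                    busco_missing=float(cols[4]),
                )
            )
    return metas


def write_busco_table(metas: Iterable[GenomeMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tspecies_code\tcomplete\tfragmented\tmissing\n")
        for m in metas:
            fh.write(
                f"{m.genome_id}\t{m.species_code}\t{m.busco_complete:.2f}"
                f"\t{m.busco_fragmented:.2f}\t{m.busco_missing:.2f}\n"
            )


def read_interproscan_tsv(path: str | Path) -> list[InterProAnnotation]:
    """Read a 4-column InterProScan-style TSV: seq id, signature accession,
    signature description, entry type.  (seq_id, signature_id) pairs are
    deduplicated, keeping the first occurrence."""
    out: list[InterProAnnotation] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            key = (cols[0], cols[1])
            if key in seen:
                continue
            seen.add(key)
            out.append(
                InterProAnnotation(
                    seq_id=cols[0],
                    signature_id=cols[1],
                    signature_name=cols[2] if len(cols) > 2 else "",
                    entry_type=cols[3] if len(cols) > 3 else "",
                )
            )
    return out


def read_gff3_mrna_parents(path: str | Path) -> dict[str, str]:
    """Optional GFF3 support for QC: map mRNA/transcript ID -> parent gene ID.

    Only ``mRNA``/``transcript`` features are consulted; this is enough to
    group isoforms by gene when sequence ids carry no recognizable suffix
    convention.  Sequence extraction from genomic GFF3 is out of scope.
    """
    parents: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] not in ("mRNA", "transcript"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if "ID" in attrs and "Parent" in attrs:
                parents[attrs["ID"]] = attrs["Parent"]
    return parents


def read_newick(path: str | Path, species_of: dict[str, str] | None = None):
    """Read a Newick gene tree (support values tolerated and ignored)."""
    from .homology import parse_newick  # deferred: homology imports this module

    return parse_newick(Path(path).read_text(), species_of)


def read_membership_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a cluster membership TSV: cluster_id, cluster_name, seq_id."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("cluster_id"):
                continue
            cols = line.split("\t")
            rows.append((cols[0], cols[1], cols[2]))
    return rows


def write_membership_tsv(
    rows: Iterable[Sequence[str]], path: str | Path, header: Sequence[str]
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


# ---------------------------------------------------------------------------
# QC and isoform filtering


def locus_of(seq_id: str, locus_pattern: str = DEFAULT_LOCUS_PATTERN) -> str:
    """Extract the locus id from a sequence id by stripping the isoform suffix.

    The pattern must expose one capture group; ids that do not match are their
    own locus.
    """
    m = re.match(locus_pattern, seq_id)
    return m.group(1) if m else seq_id


def check_dataset(
    cds: Sequence[ProteinSequence],
    proteins: Sequence[ProteinSequence],
    genome_id: str = "",
    locus_pattern: str = DEFAULT_LOCUS_PATTERN,
) -> QcReport:
    """Check that a genome's CDS and protein sets are consistent.

    Counts are compared, and locus tags (seq ids after isoform-suffix
    stripping) are matched between the two sides.  The mismatch count is the
    larger of the two one-sided set differences.  QC never raises on content.
    """
    cds_loci = {locus_of(s.seq_id, locus_pattern) for s in cds}
    prot_loci = {locus_of(s.seq_id, locus_pattern) for s in proteins}
    n_mismatch = max(len(cds_loci - prot_loci), len(prot_loci - cds_loci))
    gid = genome_id or (proteins[0].genome_id if proteins else "")
    return QcReport(
        genome_id=gid,
        n_cds=len(cds),
        n_proteins=len(proteins),
        n_locus_mismatches=n_mismatch,
    )


def filter_longest_isoform(
    proteins: Sequence[ProteinSequence],
    locus_pattern: str = DEFAULT_LOCUS_PATTERN,
) -> list[ProteinSequence]:
    """Keep one sequence per locus: the longest, ties broken by smallest seq_id.

    If the pattern matches no id at all the input is passed through unchanged
    (with a warning) — the ids carry no recognizable isoform convention.
    """
    if proteins and not any(re.match(locus_pattern, s.seq_id) for s in proteins):
        import warnings

        warnings.warn(
            "isoform pattern matched no sequence ids; passing input through",
            stacklevel=2,
        )
        return list(proteins)
    by_locus: dict[str, ProteinSequence] = {}
    for s in proteins:
        locus = locus_of(s.seq_id, locus_pattern)
        cur = by_locus.get(locus)
        if (
            cur is None
            or len(s) > len(cur)
            or (len(s) == len(cur) and s.seq_id < cur.seq_id)
        ):
            by_locus[locus] = s
    kept = {s.seq_id for s in by_locus.values()}
    return [s for s in proteins if s.seq_id in kept]
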