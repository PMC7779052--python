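import random
import string

import numpy as np
import pytest

from pangene_forge.distances import Alignment
from pangene_forge.io_formats import GenomeMeta, ProteinSequence

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return random.Random(20240917)


def random_alignment(rng, max_rows=8, max_cols=60, gap_frac=0.3, genomes=None):
    """A random gapped alignment; one row per genome when genomes is given."""
    n_rows = rng.randint(2, max_rows)
    n_cols = rng.randint(3, max_cols)
    rows = []
    for i in range(n_rows):
        chars = [
            "-" if rng.random() < gap_frac else rng.choice(AA)
            for _ in range(n_cols)
        ]
        gid = genomes[i] if genomes else f"g{i}"
        rows.append((f"s{i}", gid, "".join(chars)))
    return Alignment(rows=tuple(rows))


def make_seq(seq_id, genome_id, residues):
    return ProteinSequence(seq_id=seq_id, genome_id=genome_id, residues=residues)


def make_meta(genome_id, species="spaaa", complete=95.0, fragmented=2.0, missing=3.0):
    return GenomeMeta(
        genome_id=genome_id,
        species_code=species,
        busco_complete=complete,
        busco_fragmented=fragmented,
        busco_missing=missing,
    )


@pytest.fixture
def tiny_metas():
    return [
        make_meta("gA", complete=98.0),
        make_meta("gB", complete=95.0),
        make_meta("gC", complete=90.0),
    ]
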