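import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pangene_forge.align import progressive_align
from pangene_forge.distances import Alignment, DistanceMatrix, distance_matrix
from pangene_forge.io_formats import Hit
from pangene_forge.pangene import (
    PANGENE_ID_RE,
    ClusterKind,
    Compartment,
    Pangene,
    SequenceCluster,
    assign_ids,
    build_consensus,
    build_pangenes,
    classify_cluster,
    classify_compartment,
    rank_genomes,
    rescue_singletons,
    select_genotype_representative,
    select_representative,
)

from conftest import AA, make_meta, make_seq, random_alignment
from oracles import (
    consensus_brute,
    genotype_representative_brute,
    representative_brute,
)


class TestClassifyCluster:
    def test_one_member_is_singleton(self):
        assert classify_cluster([make_seq("a", "gA", "M")], 3) == ClusterKind.SINGLETON

    def test_one_per_genome_is_single_copy(self):
        members = [make_seq(f"s{g}", g, "MKV") for g in "ABC"]
        assert classify_cluster(members, 3) == ClusterKind.SINGLE_COPY

    def test_genome_multiplicity_two_is_multi_copy(self):
        members = [
            make_seq("a1", "gA", "M"),
            make_seq("a2", "gA", "M"),
            make_seq("b1", "gB", "M"),
            make_seq("c1", "gC", "M"),
        ]
        assert classify_cluster(members, 3) == ClusterKind.MULTI_COPY

    def test_single_genome_is_genotype_specific(self):
        members = [make_seq("a1", "gA", "M"), make_seq("a2", "gA", "M")]
        assert classify_cluster(members, 3) == ClusterKind.GENOTYPE_SPECIFIC

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            classify_cluster([], 3)


class TestRankGenomes:
    def test_complete_descending(self):
        metas = [make_meta("B", complete=87.8), make_meta("A", complete=95.5)]
        assert rank_genomes(metas) == ["A", "B"]

    def test_fragmented_breaks_complete_tie(self):
        metas = [
            make_meta("B", complete=95.0, fragmented=1.0),
            make_meta("A", complete=95.0, fragmented=2.0),
        ]
        assert rank_genomes(metas) == ["A", "B"]

    def test_missing_then_lexicographic(self):
        metas = [
            make_meta("B", complete=95.0, fragmented=2.0, missing=3.0),
            make_meta("A", complete=95.0, fragmented=2.0, missing=3.0),
            make_meta("C", complete=95.0, fragmented=2.0, missing=2.0),
        ]
        assert rank_genomes(metas) == ["C", "A", "B"]


def _dm_from(ids, entries):
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in entries.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=list(ids), d=d)


class TestSelectRepresentative:
    def test_smallest_sum_wins(self):
        members = [
            make_seq("a1", "gA", "M"),
            make_seq("a2", "gA", "M"),
            make_seq("b1", "gB", "M"),
            make_seq("c1", "gC", "M"),
        ]
        dm = _dm_from(
            ["a1", "a2", "b1", "c1"],
            {("a1", "b1"): 0.1, ("a1", "c1"): 0.2, ("a2", "b1"): 0.3, ("a2", "c1"): 0.2},
        )
        cluster = SequenceCluster("c1", "spaaa", members, ClusterKind.MULTI_COPY)
        assert select_representative(cluster, dm)["gA"] == "a1"

    def test_tie_takes_smallest_seq_id(self):
        members = [
            make_seq("a2", "gA", "M"),
            make_seq("a1", "gA", "M"),
            make_seq("b1", "gB", "M"),
        ]
        dm = _dm_from(["a2", "a1", "b1"], {("a1", "b1"): 0.5, ("a2", "b1"): 0.5})
        cluster = SequenceCluster("c1", "spaaa", members, ClusterKind.MULTI_COPY)
        assert select_representative(cluster, dm)["gA"] == "a1"

    def test_matches_exhaustive_oracle_on_random_clusters(self, rng):
        for _ in range(200):
            n = rng.randint(3, 8)
            n_genomes = rng.randint(2, 4)
            members = []
            for i in range(n):
                g = f"g{rng.randrange(n_genomes)}"
                members.append((f"s{i}", g))
            if len({g for _, g in members}) < 2:
                members[0] = (members[0][0], "gX")
            ids = [s for s, _ in members]
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = round(rng.random() * 2, 3)
            dm = DistanceMatrix(ids=ids, d=d)
            seqs = [make_seq(s, g, "M") for s, g in members]
            cluster = SequenceCluster("c", "spaaa", seqs, ClusterKind.MULTI_COPY)
            got = select_representative(cluster, dm)
            want = representative_brute(members, ids, d.tolist())
            assert got == want


class TestSelectGenotypeRepresentative:
    def test_lowest_mean_distance(self):
        members = [make_seq(s, "gA", "M") for s in ("x", "y", "z")]
        dm = _dm_from(
            ["x", "y", "z"],
            {("x", "y"): 0.15, ("x", "z"): 0.25, ("y", "z"): 0.05},
        )
        cluster = SequenceCluster("c", "spaaa", members, ClusterKind.GENOTYPE_SPECIFIC)
        assert select_genotype_representative(cluster, dm) == "y"

    def test_two_members_tie_takes_smallest_id(self):
        members = [make_seq("b", "gA", "M"), make_seq("a", "gA", "M")]
        dm = _dm_from(["b", "a"], {("a", "b"): 0.4})
        cluster = SequenceCluster("c", "spaaa", members, ClusterKind.GENOTYPE_SPECIFIC)
        assert select_genotype_representative(cluster, dm) == "a"

    def test_matches_brute_force_means(self, rng):
        for _ in range(200):
            n = rng.randint(2, 8)
            ids = [f"s{i}" for i in range(n)]
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = round(rng.random(), 3)
            dm = DistanceMatrix(ids=ids, d=d)
            seqs = [make_seq(s, "gA", "M") for s in ids]
            cluster = SequenceCluster("c", "spaaa", seqs, ClusterKind.GENOTYPE_SPECIFIC)
            got = select_genotype_representative(cluster, dm)
            want = genotype_representative_brute([(s, "gA") for s in ids], ids, d.tolist())
            assert got == want


class TestBuildConsensus:
    RANK = ["gA", "gB", "gC"]

    def test_unanimity(self):
        aln = Alignment(rows=tuple((f"s{g}", f"g{g}", "MKV") for g in "ABC"))
        assert build_consensus(aln, self.RANK) == "MKV"

    def test_majority(self):
        aln = Alignment(
            rows=(("s1", "gA", "A"), ("s2", "gB", "A"), ("s3", "gC", "C"))
        )
        assert build_consensus(aln, self.RANK) == "A"

    def test_gap_majority_drops_column(self):
        aln = Alignment(
            rows=(("s1", "gA", "AM"), ("s2", "gB", "-M"), ("s3", "gC", "-M"))
        )
        assert build_consensus(aln, self.RANK) == "M"

    def test_gap_residue_tie_keeps_column(self):
        # 1 gap vs 1 residue in a 2-row column: not strictly more gaps
        aln = Alignment(rows=(("s1", "gA", "AM"), ("s2", "gB", "-M")))
        assert build_consensus(aln, ["gA", "gB"]) == "AM"

    def test_busco_rank_breaks_residue_tie(self):
        aln = Alignment(rows=(("s1", "gA", "A"), ("s2", "gC", "C")))
        assert build_consensus(aln, ["gC", "gA"]) == "C"
        assert build_consensus(aln, ["gA", "gC"]) == "A"

    def test_all_columns_dropped_is_degenerate(self):
        aln = Alignment(
            rows=(("s1", "gA", "A-"), ("s2", "gB", "--"), ("s3", "gC", "--"))
        )
        with pytest.raises(ValueError, match="degenerate"):
            build_consensus(aln, self.RANK)

    def test_permutation_invariant_to_row_order(self, rng):
        for _ in range(50):
            genomes = [f"g{i}" for i in range(rng.randint(2, 6))]
            aln = random_alignment(rng, max_rows=len(genomes), genomes=genomes)
            rows = [r for r in aln.rows if r[1] in genomes]
            ranking = sorted(genomes, key=lambda g: rng.random())
            try:
                ref = build_consensus(Alignment(rows=tuple(rows)), ranking)
            except ValueError:
                continue
            shuffled = rows[:]
            rng.shuffle(shuffled)
            assert build_consensus(Alignment(rows=tuple(shuffled)), ranking) == ref

    @given(st.text(alphabet=AA, min_size=1, max_size=40), st.integers(2, 6))
    @settings(derandomize=True, max_examples=50)
    def test_identical_rows_reproduce_the_sequence(self, seq, n_rows):
        aln = Alignment(
            rows=tuple((f"s{i}", f"g{i}", seq) for i in range(n_rows))
        )
        assert build_consensus(aln, [f"g{i}" for i in range(n_rows)]) == seq

    def test_no_gaps_and_bounded_length(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, gap_frac=0.4)
            ranking = sorted({r[1] for r in aln.rows})
            try:
                cons = build_consensus(aln, ranking)
            except ValueError:
                continue
            assert "-" not in cons
            assert len(cons) <= aln.n_columns


class TestRescueSingletons:
    S2SP = {"q1": "spaaa", "r1": "oryza", "m1": "maize", "a2": "spaaa"}

    def _hit(self, q, s):
        return Hit(q, s, 90.0, 1e-30, 100.0)

    def test_two_foreign_species_keeps(self):
        kept, excl = rescue_singletons(
            [make_seq("q1", "gA", "M")],
            [self._hit("q1", "r1"), self._hit("q1", "m1")],
            self.S2SP,
        )
        assert [s.seq_id for s in kept] == ["q1"]
        assert not excl

    def test_own_species_hits_do_not_count(self):
        kept, excl = rescue_singletons(
            [make_seq("q1", "gA", "M")], [self._hit("q1", "a2")], self.S2SP
        )
        assert not kept and [s.seq_id for s in excl] == ["q1"]

    def test_many_hits_in_one_species_insufficient(self):
        hits = [self._hit("q1", "r1") for _ in range(5)]
        kept, excl = rescue_singletons([make_seq("q1", "gA", "M")], hits, self.S2SP)
        assert not kept


class TestIdsAndCompartments:
    def _pangene(self, genomes, roles=None):
        roles = roles or ["rep"] * len(genomes)
        return Pangene(
            pangene_id="",
            species_code="musac",
            sequence="MKV",
            members=[(f"s{i}", g, r) for i, (g, r) in enumerate(zip(genomes, roles))],
            compartment=Compartment.DISPENSABLE,
            source_kind=ClusterKind.SINGLE_COPY,
        )

    def test_ids_dense_from_000001_and_match_regex(self):
        pgs = [self._pangene(["gA"]) for _ in range(3)]
        out = assign_ids(pgs, "musac")
        assert [p.pangene_id for p in out] == [
            "musac_pan_p000001",
            "musac_pan_p000002",
            "musac_pan_p000003",
        ]
        assert all(PANGENE_ID_RE.match(p.pangene_id) for p in out)

    def test_paper_style_id_shape(self):
        assert PANGENE_ID_RE.match("musac_pan_p029014")

    def test_empty_list(self):
        assert assign_ids([], "musac") == []

    def test_core_requires_every_genome(self):
        pg = self._pangene(["gA", "gB", "gC", "gD"])
        assert classify_compartment(pg, ["gA", "gB", "gC", "gD"]) == Compartment.CORE
        assert (
            classify_compartment(pg, ["gA", "gB", "gC", "gD", "gE"])
            == Compartment.DISPENSABLE
        )

    def test_single_genome_species_always_core(self):
        pg = self._pangene(["gA"])
        assert classify_compartment(pg, ["gA"]) == Compartment.CORE

    def test_monotone_adding_genome_never_flips_core_to_dispensable(self, rng):
        all_genomes = ["gA", "gB", "gC", "gD"]
        for _ in range(50):
            present = [g for g in all_genomes if rng.random() < 0.6] or ["gA"]
            pg = self._pangene(present)
            before = classify_compartment(pg, all_genomes)
            extra = rng.choice(all_genomes)
            pg2 = self._pangene(present + [extra])
            after = classify_compartment(pg2, all_genomes)
            if before == Compartment.CORE:
                assert after == Compartment.CORE

    def test_paralog_roles_do_not_define_presence(self):
        pg = self._pangene(["gA", "gB"], roles=["rep", "p"])
        assert classify_compartment(pg, ["gA", "gB"]) == Compartment.DISPENSABLE


class TestConsensusOracle:
    def test_consensus_equals_brute_force(self, rng):
        ok = 0
        for _ in range(200):
            n_rows = rng.randint(2, 10)
            genomes = [f"g{i}" for i in range(n_rows)]
            aln = random_alignment(
                rng, max_rows=n_rows, max_cols=60, gap_frac=0.6 * rng.random(),
                genomes=genomes,
            )
            ranking = sorted(genomes, key=lambda g: rng.random())
            try:
                got = build_consensus(aln, ranking)
            except ValueError:
                got = None
            want = consensus_brute(list(aln.rows), ranking) or None
            assert got == want
            ok += 1
        assert ok == 200


class TestBuildPangenes:
    def _metas(self):
        return [
            make_meta("gA", complete=98.0),
            make_meta("gB", complete=95.0),
            make_meta("gC", complete=90.0),
        ]

    def test_multi_copy_flow_labels_rep_and_p(self):
        base = "".join(random.Random(3).choice(AA) for _ in range(40))
        variant = "A" * 12 + base[12:]
        members = [
            make_seq("a1", "gA", base),
            make_seq("a2", "gA", variant),
            make_seq("b1", "gB", base),
            make_seq("c1", "gC", base),
        ]
        cluster = SequenceCluster(
            "c001", "spaaa", members, classify_cluster(members, 3)
        )
        assert cluster.kind == ClusterKind.MULTI_COPY
        pangenes, stats, excluded = build_pangenes(
            [cluster], self._metas(), progressive_align
        )
        assert len(pangenes) == 1
        roles = dict((sid, role) for sid, _, role in pangenes[0].members)
        assert roles == {"a1": "rep", "a2": "p", "b1": "rep", "c1": "rep"}
        assert pangenes[0].compartment == Compartment.CORE
        assert pangenes[0].sequence == base

    def test_every_sequence_conserved_in_members_or_excluded(self):
        base = "".join(random.Random(5).choice(AA) for _ in range(30))
        clusters = [
            SequenceCluster(
                "c001",
                "spaaa",
                [make_seq(f"s{g}", f"g{g}", base) for g in "ABC"],
                ClusterKind.SINGLE_COPY,
            ),
            SequenceCluster(
                "c002",
                "spaaa",
                [make_seq("lonely", "gA", base)],
                ClusterKind.SINGLETON,
            ),
        ]
        pangenes, stats, excluded = build_pangenes(
            [cluster for cluster in clusters], self._metas(), progressive_align
        )
        placed = {sid for p in pangenes for sid, _, _ in p.members}
        placed |= {s.seq_id for s in excluded}
        assert placed == {"sA", "sB", "sC", "lonely"}

    def test_excluded_singleton_percentage(self):
        base = "".join(random.Random(7).choice(AA) for _ in range(30))
        members = [make_seq(f"s{i}", f"g{g}", base) for i, g in enumerate("ABC")]
        clusters = [
            SequenceCluster("c001", "spaaa", members, ClusterKind.SINGLE_COPY),
            SequenceCluster(
                "c002", "spaaa", [make_seq("x", "gA", base)], ClusterKind.SINGLETON
            ),
        ]
        _, stats, excluded = build_pangenes(clusters, self._metas(), progressive_align)
        assert len(excluded) == 1
        assert stats.pct_singletons_excluded == pytest.approx(100.0 / 4)

    def test_genotype_specific_keeps_representative_verbatim(self):
        base = "".join(random.Random(11).choice(AA) for _ in range(30))
        variant = "AC" + base[2:]
        members = [make_seq("a1", "gA", base), make_seq("a2", "gA", variant)]
        cluster = SequenceCluster(
            "c001", "spaaa", members, ClusterKind.GENOTYPE_SPECIFIC
        )
        pangenes, _, _ = build_pangenes([cluster], self._metas(), progressive_align)
        assert pangenes[0].sequence in (base, variant)
        assert pangenes[0].compartment == Compartment.DISPENSABLE
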