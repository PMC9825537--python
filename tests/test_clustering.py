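"""Binary assembly similarity, clustering, and evidence statistics."""

import dataclasses

import numpy as np
import pytest

from conftest import random_rigid_motion, transform_assembly
from quatclust.assemblies import connecting_interfaces, unique_interfaces
from quatclust.clustering import (
    AssemblyCluster,
    ClusterMember,
    DataInconsistencyError,
    IncomparableError,
    annotation_agreement,
    assembly_similarity,
    cluster_assemblies,
    identity_stats,
    r_cf_unpclus,
)
from quatclust.fixtures import (
    make_cyclic,
    make_dihedral,
    make_side_tetramer,
    mutate_sequence,
)
from quatclust.interfaces import qscore
from quatclust.pfam_arch import assembly_architecture
from quatclust.symmetry_stoich import detect_point_group, stoichiometry


def annotate(asm, entry_id=None):
    asm.pfam_assembly_arch = assembly_architecture(
        [c.arch or "(NA)" for c in asm.chains]
    )
    asm.stoichiometry = stoichiometry(asm, "by_arch")
    asm.symmetry = detect_point_group(asm, "pseudo_by_arch").label
    if entry_id:
        asm.entry_id = entry_id
    return asm


@pytest.fixture()
def alpha(template):
    return annotate(make_dihedral(template, 2, assembly_id="alpha"), "E1")


@pytest.fixture()
def beta(template):
    return annotate(make_side_tetramer(template, assembly_id="beta"), "E2")


class TestBinarySimilarity:
    def test_reflexive(self, alpha):
        assert assembly_similarity(alpha, alpha).s == 1

    def test_symmetric(self, alpha, beta):
        ab = assembly_similarity(alpha, beta)
        ba = assembly_similarity(beta, alpha)
        assert ab.s == ba.s
        assert (ab.s12, ab.s21) == (ba.s21, ba.s12)

    def test_incompatible_tetramers_differ(self, template, alpha, beta):
        assert assembly_similarity(alpha, beta).s == 0
        # oracle: explicit Q between all unique-interface representatives
        ca, cb = connecting_interfaces(alpha), connecting_interfaces(beta)
        ia = {i.interface_id: i for i in alpha.interfaces}
        ib = {i.interface_id: i for i in beta.interfaces}
        stack = ia[ca.connecting[-1]]  # alpha's inter-ring interface
        assert all(
            qscore(stack, ib[r]).value < 0.5 for r in cb.representatives
        )

    def test_rigid_body_moved_copy_is_same(self, template, alpha):
        rng = np.random.default_rng(5)
        rot, trans = random_rigid_motion(rng)
        moved = annotate(transform_assembly(alpha, rot, trans), "E9")
        assert assembly_similarity(alpha, moved).s == 1

    def test_cell_gate_rejects_different_symmetry(self, template):
        c3 = annotate(make_cyclic(template, 3, assembly_id="c3"))
        c2 = annotate(make_cyclic(template, 2, assembly_id="c2"))
        with pytest.raises(IncomparableError):
            assembly_similarity(c3, c2)


class TestClusterAssemblies:
    def test_three_copies_three_cfs(self, template):
        asms = [
            annotate(make_cyclic(template, 3, assembly_id=f"a{k}"), f"E{k}")
            for k in range(3)
        ]
        clusters = cluster_assemblies(asms, {f"E{k}": k for k in range(3)})
        assert len(clusters) == 1
        assert clusters[0].n_cfs == 3

    def test_two_tetramer_faces_make_two_clusters(self, template):
        asms = [
            annotate(make_dihedral(template, 2, assembly_id="a1"), "E1"),
            annotate(make_dihedral(template, 2, assembly_id="a2"), "E2"),
            annotate(make_side_tetramer(template, assembly_id="b1"), "E3"),
            annotate(make_side_tetramer(template, assembly_id="b2"), "E4"),
        ]
        clusters = cluster_assemblies(asms, {f"E{k}": k for k in range(1, 5)})
        assert len(clusters) == 2
        members = sorted(
            tuple(sorted(m.assembly.assembly_id for m in c.members)) for c in clusters
        )
        assert members == [("a1", "a2"), ("b1", "b2")]

    def test_different_cells_never_mix(self, template):
        asms = [
            annotate(make_cyclic(template, 3, assembly_id="t1"), "E1"),
            annotate(make_cyclic(template, 2, assembly_id="d1"), "E2"),
        ]
        clusters = cluster_assemblies(asms, {"E1": 0, "E2": 1})
        assert len(clusters) == 2
        assert {c.stoichiometry for c in clusters} == {"A3", "A2"}

    def test_partition_and_input_order_invariance(self, template):
        asms = [
            annotate(make_dihedral(template, 2, assembly_id="a1"), "E1"),
            annotate(make_side_tetramer(template, assembly_id="b1"), "E2"),
            annotate(make_cyclic(template, 2, assembly_id="d1"), "E3"),
        ]
        cfs = {"E1": 0, "E2": 1, "E3": 2}
        ref = [
            (c.arch, c.stoichiometry, sorted(m.assembly.assembly_id for m in c.members))
            for c in cluster_assemblies(asms, cfs)
        ]
        got = [
            (c.arch, c.stoichiometry, sorted(m.assembly.assembly_id for m in c.members))
            for c in cluster_assemblies(list(reversed(asms)), cfs)
        ]
        assert ref == got
        all_members = [m for c in cluster_assemblies(asms, cfs) for m in c.members]
        assert len(all_members) == len(asms)

    def test_rigid_body_motion_changes_nothing(self, template):
        rng = np.random.default_rng(21)
        rot, trans = random_rigid_motion(rng)
        asms = [
            annotate(make_dihedral(template, 2, assembly_id="a1"), "E1"),
            annotate(make_side_tetramer(template, assembly_id="b1"), "E2"),
        ]
        moved = [
            annotate(transform_assembly(a, rot, trans), a.entry_id) for a in asms
        ]
        cfs = {"E1": 0, "E2": 1}
        ref = [len(c.members) for c in cluster_assemblies(asms, cfs)]
        got = [len(c.members) for c in cluster_assemblies(moved, cfs)]
        assert ref == got == [1, 1]


def make_cluster(members):
    """members: list of (entry, cf_id, unps)."""
    return AssemblyCluster(
        cluster_id=0,
        arch="(Tmpl)4",
        stoichiometry="A4",
        symmetry="D2",
        members=[
            ClusterMember(
                assembly=None, entry_id=e, cf_id=cf, entity_keys=frozenset(unps)
            )
            for e, cf, unps in members
        ],
        representative=members[0][0],
    )


class TestRCfUnpClus:
    def test_five_of_seven_rounds_to_0_71(self):
        cluster = make_cluster([(f"E{k}", k, ["TTHY_HUMAN"]) for k in range(5)])
        stats = r_cf_unpclus(cluster, {"TTHY_HUMAN": 7})
        assert stats.per_unp["TTHY_HUMAN"] == (5, 7, pytest.approx(5 / 7))
        assert stats.rounded() == pytest.approx(0.71)

    def test_all_corpus_cfs_in_cluster_gives_one(self):
        # 12 UniProts whose 21 corpus CFs are all in the cluster
        members, corpus = [], {}
        cf = 0
        for u in range(12):
            unp = f"UNP{u:02d}"
            n = 2 if u < 9 else 1
            for _ in range(n):
                members.append((f"E{cf}", cf, [unp]))
                cf += 1
            corpus[unp] = n
        assert cf == 21
        stats = r_cf_unpclus(make_cluster(members), corpus)
        assert stats.cluster_ratio == pytest.approx(1.0)

    def test_single_cf_unp_gives_one(self):
        stats = r_cf_unpclus(make_cluster([("E1", 0, ["U1"])]), {"U1": 1})
        assert stats.cluster_ratio == pytest.approx(1.0)

    def test_zero_corpus_count_is_inconsistent(self):
        with pytest.raises(DataInconsistencyError):
            r_cf_unpclus(make_cluster([("E1", 0, ["U1"])]), {"U1": 0})

    def test_unknown_unps_do_not_contribute(self):
        cluster = make_cluster([("E1", 0, ["U1"]), ("E2", 1, ["UX"])])
        stats = r_cf_unpclus(cluster, {"U1": 2})
        assert stats.per_unp.keys() == {"U1"}
        assert stats.cluster_ratio == pytest.approx(0.5)


class TestAnnotationAgreement:
    def test_matching_annotation_counted_and_subassembly_not(self, template):
        tet1 = annotate(make_dihedral(template, 2, assembly_id="t1"), "E1")
        tet2 = annotate(make_dihedral(template, 2, assembly_id="t2"), "E2")
        clusters = cluster_assemblies([tet1, tet2], {"E1": 0, "E2": 1})
        cluster = clusters[0]
        annotated_tet = annotate(make_dihedral(template, 2, assembly_id="pdb1"), "E1")
        annotated_dimer = annotate(make_cyclic(template, 2, assembly_id="pdb2"), "E2")
        counts = annotation_agreement(
            cluster,
            {"E1": {"PDB": [annotated_tet]}, "E2": {"PDB": [annotated_dimer]}},
        )
        assert counts == {"PDB": 1}  # the half-tetramer fails the cell gate


class TestIdentityStats:
    def test_identical_sequences_intra_100(self, template):
        asms = [
            annotate(make_cyclic(template, 2, assembly_id=f"a{k}"), f"E{k}")
            for k in range(3)
        ]
        # distinct entity labels with the same sequence
        for k, a in enumerate(asms):
            a.chains = [
                dataclasses.replace(c, entity_key=f"U{k}{i}")
                for i, c in enumerate(a.chains)
            ]
        clusters = cluster_assemblies(asms, {f"E{k}": k for k in range(3)})
        intra, inter = identity_stats(clusters, min_cfs=3)
        assert intra == [pytest.approx(100.0)]
        assert inter == []

    def test_unrelated_clusters_low_inter_identity(self, template):
        from quatclust.fixtures import make_template_chain

        other = make_template_chain(30, seed=99, entity_key="UNPZ")
        group_a = [
            annotate(make_cyclic(template, 2, assembly_id=f"a{k}"), f"E{k}")
            for k in range(3)
        ]
        group_b = [
            annotate(make_side_tetramer(other, assembly_id=f"b{k}"), f"F{k}")
            for k in range(3)
        ]
        cfs = {f"E{k}": k for k in range(3)} | {f"F{k}": 10 + k for k in range(3)}
        clusters = cluster_assemblies(group_a + group_b, cfs)
        intra, inter = identity_stats(clusters, min_cfs=3)
        assert inter  # one cross-cluster comparison
        assert all(v < 35.0 for v in inter)
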