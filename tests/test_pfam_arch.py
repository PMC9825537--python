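"""Architecture strings, HMM maps, and alignment-based position maps."""

import numpy as np
import pytest

from quatclust.pfam_arch import (
    AssignmentConflictError,
    DomainAssignment,
    assembly_architecture,
    chain_architecture,
    entry_architecture,
    pairwise_position_map,
    parse_architecture,
    read_assignment_table,
    residue_to_hmm_map,
)


def asgn(pfam, start, end, dom=None, hmm=None):
    return DomainAssignment(
        entry_id="E1",
        chain_id="A",
        pfam_id=pfam,
        seq_start=start,
        seq_end=end,
        dom_start=dom[0] if dom else None,
        dom_end=dom[1] if dom else None,
        hmm_map=hmm or {},
    )


class TestChainArchitecture:
    def test_two_domain_chain(self):
        arch = chain_architecture([asgn("Cyclin_N", 1, 100), asgn("Cyclin_C", 110, 200)])
        assert arch == "(Cyclin_N)_(Cyclin_C)"

    def test_single_domain(self):
        assert chain_architecture([asgn("Pkinase", 5, 260)]) == "(Pkinase)"

    def test_split_domain_with_insertions(self):
        parts = [
            asgn("IMPDH", 1, 90, dom=(1, 82)),
            asgn("CBS", 95, 150),
            asgn("CBS", 155, 210),
            asgn("IMPDH", 215, 500, dom=(83, 345)),
        ]
        assert (
            chain_architecture(parts)
            == "(IMPDH[1–82])_(CBS)_(CBS)_(IMPDH[83–345])"
        )

    def test_large_overlap_rejected(self):
        with pytest.raises(AssignmentConflictError):
            chain_architecture([asgn("A", 1, 100), asgn("B", 50, 150)])

    def test_no_assignment_gives_na(self):
        assert chain_architecture([]) == "(NA)"


class TestEntryAndAssemblyArchitecture:
    def test_entry_concatenates_unique_archs(self):
        archs = ["(Pkinase)", "(Cyclin_N)_(Cyclin_C)"]
        assert entry_architecture(archs) == "(Cyclin_N)_(Cyclin_C)(Pkinase)"

    def test_entry_dedupes_repeats(self):
        assert entry_architecture(["(Pkinase)", "(Pkinase)"]) == "(Pkinase)"

    def test_two_sequences_same_arch_collapse(self):
        assert entry_architecture(["(Iso_dh)", "(Iso_dh)", "(Iso_dh)"]) == "(Iso_dh)"

    def test_assembly_homodimer(self):
        assert assembly_architecture(["(Pkinase)", "(Pkinase)"]) == "(Pkinase)2"

    def test_assembly_2to2_complex(self):
        archs = ["(Pkinase)", "(Pkinase)", "(Cyclin_N)_(Cyclin_C)", "(Cyclin_N)_(Cyclin_C)"]
        assert assembly_architecture(archs) == "(Cyclin_N)_(Cyclin_C)2(Pkinase)2"

    def test_assembly_monomer(self):
        assert assembly_architecture(["(Pkinase)"]) == "(Pkinase)"

    @pytest.mark.parametrize(
        "arch,expected",
        [
            ("(Pkinase)2", [("Pkinase", None, 2)]),
            ("(Cyclin_N)_(Cyclin_C)", [("Cyclin_N", None, 1), ("Cyclin_C", None, 1)]),
            (
                "(IMPDH[1–82])_(CBS)_(CBS)_(IMPDH[83–345])",
                [
                    ("IMPDH", (1, 82), 1),
                    ("CBS", None, 1),
                    ("CBS", None, 1),
                    ("IMPDH", (83, 345), 1),
                ],
            ),
        ],
    )
    def test_grammar_round_trips(self, arch, expected):
        assert parse_architecture(arch) == expected


class TestResidueToHmmMap:
    def test_full_coverage_identity_map(self):
        a = asgn("X", 1, 10, hmm={p: p for p in range(1, 11)})
        assert residue_to_hmm_map([a]) == {p: ("X", p) for p in range(1, 11)}

    def test_insertion_positions_unmapped(self):
        hmm = {p: p for p in range(1, 6)} | {p: p - 5 + 5 for p in range(11, 16)}
        a = asgn("X", 1, 15, hmm={p: p for p in range(1, 6)} | {p: p - 5 for p in range(11, 16)})
        mapping = residue_to_hmm_map([a])
        for p in range(6, 11):
            assert p not in mapping

    def test_two_domains_union(self):
        a = asgn("X", 1, 10, hmm={p: p for p in range(1, 11)})
        b = asgn("Y", 21, 30, hmm={p: p - 20 for p in range(21, 31)})
        mapping = residue_to_hmm_map([a, b])
        assert set(mapping) == set(range(1, 11)) | set(range(21, 31))
        assert mapping[25] == ("Y", 5)

    def test_conflicting_columns_rejected(self):
        a = asgn("X", 1, 10, hmm={5: 5})
        b = asgn("X", 1, 10, hmm={5: 6})
        with pytest.raises(AssignmentConflictError):
            residue_to_hmm_map([a, b])


def simple_needleman_wunsch(a, b, match=1.0, mismatch=-1.0, gap_open=-10.0, gap_ext=-0.5):
    """Independent affine-gap DP (Gotoh) computing the optimal score only."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_ext * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_ext)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_ext)
    return max(M[n, m], X[n, m], Y[n, m])


class TestPairwisePositionMap:
    def test_identical_sequences_identity_map(self):
        seq = "ACDEFHIKLM"
        mapping, identity = pairwise_position_map(seq, seq)
        assert mapping == {i: i for i in range(1, 11)}
        assert identity == pytest.approx(1.0)

    def test_internal_deletion_skips_deleted_positions(self):
        seq_a = "ACDEFHIKLM"
        seq_b = seq_a[:4] + seq_a[6:]  # delete positions 5-6
        mapping, _ = pairwise_position_map(seq_a, seq_b)
        assert 5 not in mapping and 6 not in mapping
        assert all(mapping[p] == p for p in range(1, 5))
        assert all(mapping[p] == p - 2 for p in range(7, 11))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_score_matches_independent_dp(self, seed):
        rng = np.random.default_rng(seed)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(letters, size=25))
        b = "".join(rng.choice(letters, size=22))
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        assert aligner.score(a, b) == pytest.approx(simple_needleman_wunsch(a, b))

    def test_unrelated_sequences_low_identity_total_map(self):
        rng = np.random.default_rng(42)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(letters, size=60))
        b = "".join(rng.choice(letters, size=60))
        mapping, identity = pairwise_position_map(a, b)
        assert identity < 0.35  # near random-alignment background
        # the map is total on aligned columns and strictly increasing
        keys = sorted(mapping)
        vals = [mapping[k] for k in keys]
        assert vals == sorted(vals)


class TestAssignmentTable:
    def test_round_trip_table(self, tmp_path):
        path = tmp_path / "domains.tsv"
        path.write_text(
            "# entry\tchain\tpfam\tstart\tend\tdom_start\tdom_end\tmap\n"
            "E1\tA\tPkinase\t1\t10\t-\t-\t1:1,2:2,3:3\n"
            "E1\tB\tIMPDH\t1\t90\t1\t82\t\n"
        )
        table = read_assignment_table(path)
        a = table[("E1", "A")][0]
        assert a.pfam_id == "Pkinase"
        assert a.hmm_map == {1: 1, 2: 2, 3: 3}
        b = table[("E1", "B")][0]
        assert (b.dom_start, b.dom_end) == (1, 82)
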