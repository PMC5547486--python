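"""Domain mapping, identity profiling, conservation classes, consensus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sinaphy.conservation import (DomainMap, build_consensus,
                                  check_invariant_residues, column_classes,
                                  compare_consensus, consensus_joint_alignment,
                                  map_domains_to_columns, percent_identity,
                                  read_domain_maps, unanimous_count,
                                  write_domain_maps)
from sinaphy.core_io import Alignment, SequenceRecord

from conftest import random_alignment


def _aln(rows, ids=None):
    ids = ids or [f"r{i}" for i in range(len(rows))]
    return Alignment([SequenceRecord(id=i, residues=s) for i, s in zip(ids, rows)])


class TestDomainMap:
    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainMap(reference_id="r", spans={"RING": (1, 10), "SZF": (10, 20)})

    def test_round_trip_tsv(self, tmp_path):
        maps = {"SIAH1": DomainMap(reference_id="h1",
                                   spans={"RING": (41, 76), "SBS": (151, 175)})}
        path = tmp_path / "maps.tsv"
        write_domain_maps(maps, path)
        back = read_domain_maps(path)
        assert back["SIAH1"].spans == maps["SIAH1"].spans
        assert back["SIAH1"].reference_id == "h1"


class TestDomainMapping:
    def test_gapless_reference_identity_map(self):
        aln = _aln(["ACDEF", "ACDEF"], ids=["ref", "o"])
        dmap = DomainMap(reference_id="ref", spans={"RING": (2, 4)})
        assert map_domains_to_columns(aln, dmap) == {"RING": (2, 4)}

    def test_gapped_reference_shifts_columns(self):
        """Reference 'A-CD', span over residues 2-3 ('CD') -> columns 3-4."""
        aln = _aln(["A-CD", "AACD"], ids=["ref", "o"])
        dmap = DomainMap(reference_id="ref", spans={"RING": (2, 3)})
        assert map_domains_to_columns(aln, dmap) == {"RING": (3, 4)}

    def test_span_beyond_reference_rejected(self):
        aln = _aln(["A-CD", "AACD"], ids=["ref", "o"])
        dmap = DomainMap(reference_id="ref", spans={"RING": (2, 9)})
        with pytest.raises(ValueError, match="exceeds"):
            map_domains_to_columns(aln, dmap)


class TestPercentIdentity:
    def test_self_identity_is_100(self, toy_alignment):
        ident = percent_identity(toy_alignment, "ref")
        assert ident["ref"] == 100.0
        assert ident["same"] == 100.0

    def test_gaps_counted_in_denominator(self, toy_alignment):
        """3 mismatches + 1 gap over 10 columns -> 60%."""
        ident = percent_identity(toy_alignment, "ref")
        assert ident["diff3gap1"] == pytest.approx(60.0)

    def test_x_never_matches(self):
        aln = _aln(["AAAA", "AAXA"], ids=["ref", "o"])
        assert percent_identity(aln, "ref")["o"] == pytest.approx(75.0)

    def test_skip_columns_missing_in_incomplete_record(self):
        """Columns where the truncated record is gapped leave the
        denominator for every comparison."""
        aln = _aln(["ACDEFGHIKL", "ACDEF-----", "ACREF-----"],
                   ids=["ref", "trunc", "o"])
        plain = percent_identity(aln, "ref")
        assert plain["trunc"] == pytest.approx(50.0)
        adjusted = percent_identity(aln, "ref", skip_columns_missing_in="trunc")
        assert adjusted["trunc"] == pytest.approx(100.0)
        assert adjusted["o"] == pytest.approx(80.0)

    def test_symmetry_for_gap_free_pairs(self, rng):
        aln = random_alignment(rng, 4, 30, gap_prob=0.0, x_prob=0.0)
        a, b = aln.ids[0], aln.ids[1]
        assert percent_identity(aln, a)[b] == percent_identity(aln, b)[a]

    def test_unknown_id_rejected(self, toy_alignment):
        with pytest.raises(KeyError):
            percent_identity(toy_alignment, "nope")


class TestColumnClasses:
    def test_rule_evaluation(self):
        """All-K -> identical; {K,R} -> similar (one basic group);
        {K,D} -> divergent."""
        aln = _aln(["KKK", "KRD"])
        classes = column_classes(aln)["class"].tolist()
        assert classes == ["identical", "similar", "divergent"]

    def test_gap_blocks_identical_class(self):
        aln = _aln(["KK", "K-"])
        assert column_classes(aln)["class"].tolist() == ["identical", "similar"]

    @given(st.integers(0, 2**31 - 1))
    def test_classes_partition_span(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 5, 15)
        classes = column_classes(aln)
        assert len(classes) == 15
        assert set(classes["class"]) <= {"identical", "similar", "divergent"}

    def test_unanimous_count(self):
        aln = _aln(["KAD", "KAE"])
        assert unanimous_count(aln, (1, 3)) == (2, 3)


class TestInvariantResidues:
    def test_all_pass_at_conserved_positions(self):
        aln = _aln(["CACHA", "CECHE"], ids=["ref", "o"])
        ok = check_invariant_residues(aln, "ref", [1, 4], allowed="CH")
        assert ok.all()

    def test_single_perturbation_fails_one_record(self):
        aln = _aln(["CACHA", "SACHA", "CACHA"], ids=["ref", "mut", "o"])
        ok = check_invariant_residues(aln, "ref", [1, 4], allowed="CH")
        assert not ok["mut"] and ok["ref"] and ok["o"]

    def test_unmappable_position_rejected(self):
        aln = _aln(["CACHA"], ids=["ref"])
        with pytest.raises(ValueError, match="not mappable"):
            check_invariant_residues(aln, "ref", [9], allowed="CH")


class TestConsensus:
    @pytest.mark.parametrize("column,expected", [
        ("AAA", "A"),      # unanimity
        ("AACC", "X"),     # two residues tie at the top
        ("AAC", "A"),      # strict majority
    ])
    def test_majority_and_tie_rule(self, column, expected):
        aln = _aln([c for c in column], ids=[f"s{i}" for i in range(len(column))])
        assert build_consensus(aln).residues == expected

    def test_identical_records_reproduce_sequence(self):
        aln = _aln(["ACDEF"] * 4)
        cons = build_consensus(aln)
        assert cons.residues == "ACDEF"
        assert "X" not in cons.residues

    def test_gap_only_columns_dropped(self):
        aln = _aln(["A-C", "A-C"])
        cons = build_consensus(aln)
        assert cons.residues == "AC"
        assert list(cons.columns) == [1, 3]

    @given(st.integers(0, 2**31 - 1))
    def test_matches_frequency_recount_oracle(self, seed):
        """Independent per-column recount: the consensus letter is the
        unique argmax of non-gap frequencies, 'X' exactly on ties."""
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, int(rng.integers(2, 8)),
                               int(rng.integers(3, 25)), gap_prob=0.3)
        cons = build_consensus(aln)
        pos = 0
        for j in range(1, aln.n_columns + 1):
            col = [r.residues[j - 1] for r in aln.records]
            freqs = {}
            for ch in col:
                if ch != "-":
                    freqs[ch] = freqs.get(ch, 0) + 1
            if not freqs:
                continue
            top = max(freqs.values())
            winners = [c for c, n in freqs.items() if n == top]
            expected = winners[0] if len(winners) == 1 else "X"
            assert cons.residues[pos] == expected, f"column {j}"
            assert cons.columns[pos] == j
            pos += 1
        assert pos == len(cons)


class TestConsensusComparison:
    def test_self_comparison_is_100_everywhere(self):
        aln = _aln(["ACDEFGHIKL"] * 3, ids=["g1a", "g1b", "g1c"])
        cons = build_consensus(aln, source_id="G1")
        joint = consensus_joint_alignment([cons, cons], ["G1", "G2"])
        table = compare_consensus(joint, "G1", {"RING": (1, 4)})
        assert table.loc["G2", "RING"] == 100.0
        assert table.loc["G2", "WHOLE"] == 100.0

    def test_x_counts_as_mismatch(self):
        a = _aln(["AC", "AC"], ids=["x", "y"])
        b = _aln(["AC", "AG"], ids=["p", "q"])   # ties at column 2 -> X
        ca = build_consensus(a, source_id="A")
        cb = build_consensus(b, source_id="B")
        joint = consensus_joint_alignment([ca, cb], ["A", "B"])
        table = compare_consensus(joint, "A")
        assert table.loc["B", "WHOLE"] == pytest.approx(50.0)
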