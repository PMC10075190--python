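"""Constraint resolution, transfer-derived constraints, consistency, violations."""

import numpy as np
import pytest

import chronocorrect as cc
from chronocorrect.chronogram import StructureError
from chronocorrect.constraints import RedundantConstraintWarning

from conftest import constraint


class TestResolve:
    def test_mrca_pair(self, fix_a):
        R = cc.resolve([constraint("c1", ("A", "B"), ("C", "D"))], fix_a)
        assert R.resolved["c1"] == (fix_a.mrca(["A", "B"]), fix_a.mrca(["C", "D"]))

    def test_single_leaf_mrca_is_the_leaf(self, fix_a):
        R = cc.resolve([constraint("c1", ("A",), ("C", "D"))], fix_a)
        assert R.resolved["c1"] == (fix_a.leaf_id("A"), fix_a.mrca(["C", "D"]))

    def test_ancestor_descendant_excluded_with_warning(self, fix_a):
        with pytest.warns(RedundantConstraintWarning):
            R = cc.resolve(
                [constraint("c1", ("A", "B"), ("A", "B", "C", "D"))], fix_a
            )
        assert len(R) == 0
        assert len(R.excluded) == 1

    def test_unknown_taxon_raises(self, fix_a):
        with pytest.raises(StructureError, match="Z"):
            cc.resolve([constraint("c1", ("Z",), ("C", "D"))], fix_a)

    def test_duplicate_ids_rejected(self, fix_a):
        cons = [
            constraint("c1", ("A",), ("C", "D")),
            constraint("c1", ("B",), ("C", "D")),
        ]
        with pytest.raises(StructureError, match="unique"):
            cc.resolve(cons, fix_a)

    def test_tsv_round_trip(self, fix_a):
        tsv = "id\tolder\tyounger\nc1\tMRCA(A;B)\tMRCA(C;D)\n"
        cons = cc.read_constraints(tsv)
        R = cc.resolve(cons, fix_a)
        assert R.resolved["c1"] == (fix_a.mrca(["A", "B"]), fix_a.mrca(["C", "D"]))


class TestTransferDerivedConstraints:
    def test_donor_parent_older_than_recipient_child(self, fix_a):
        # transfer from the edge above leaf A into the edge above leaf C:
        # the donor edge's parent (anc(A,B)) must be older than C
        rec = cc.TransferRecord(
            id="t1",
            donor_edge_child=cc.NodeRef(taxa=("A",)),
            recipient_edge_child=cc.NodeRef(taxa=("C",)),
        )
        con = cc.constraint_from_transfer(rec, fix_a)
        R = cc.resolve([con], fix_a)
        assert R.resolved["t1"] == (fix_a.mrca(["A", "B"]), fix_a.leaf_id("C"))

    def test_donor_child_at_root_rejected(self, fix_a):
        rec = cc.TransferRecord(
            id="t1",
            donor_edge_child=cc.NodeRef(taxa=("A", "B", "C", "D")),
            recipient_edge_child=cc.NodeRef(taxa=("C",)),
        )
        with pytest.raises(StructureError, match="root"):
            cc.constraint_from_transfer(rec, fix_a)

    def test_sibling_edge_transfer_is_redundant(self, fix_a):
        # donor edge (root, anc(A,B)); recipient edge (anc(C,D), C):
        # derived constraint "root older than C" is implied by the topology
        rec = cc.TransferRecord(
            id="t1",
            donor_edge_child=cc.NodeRef(taxa=("A", "B")),
            recipient_edge_child=cc.NodeRef(taxa=("C",)),
        )
        con = cc.constraint_from_transfer(rec, fix_a)
        with pytest.warns(RedundantConstraintWarning):
            R = cc.resolve([con], fix_a)
        assert len(R) == 0

    def test_transfer_tsv(self, fix_a):
        tsv = "id\tdonor_child\trecipient_child\nt1\tMRCA(A)\tMRCA(C)\n"
        recs = cc.read_transfers(tsv)
        con = cc.constraint_from_transfer(recs[0], fix_a)
        R = cc.resolve([con], fix_a)
        assert len(R) == 1


class TestConsistency:
    def test_single_constraint_consistent(self, fix_a, u_older_v):
        assert cc.check_consistency(fix_a, u_older_v)

    def test_two_cycle_detected(self, fix_a):
        R = cc.resolve(
            [
                constraint("c1", ("A", "B"), ("C", "D")),
                constraint("c2", ("C", "D"), ("A", "B")),
            ],
            fix_a,
        )
        rep = cc.check_consistency(fix_a, R)
        assert not rep
        assert len(rep.cycle) == 2
        assert not rep.hard  # constraint-only cycle would merely force equality

    def test_cycle_through_tree_edge(self, fix_a):
        # "A older than anc(A,B)" conflicts with the tree edge anc(A,B)->A
        R = cc.ConstraintSet(
            constraints=[],
            resolved={"c1": (fix_a.leaf_id("A"), fix_a.mrca(["A", "B"]))},
        )
        rep = cc.check_consistency(fix_a, R)
        assert not rep and rep.hard

    def test_verdict_order_independent(self, fix_a):
        cons = [
            constraint("c1", ("A", "B"), ("C", "D")),
            constraint("c2", ("C",), ("A", "B")),
        ]
        r1 = cc.check_consistency(fix_a, cc.resolve(cons, fix_a))
        r2 = cc.check_consistency(fix_a, cc.resolve(cons[::-1], fix_a))
        assert r1.consistent == r2.consistent


class TestViolations:
    def test_violated_constraint_counted(self, fix_a, u_older_v):
        assert cc.count_violations(fix_a, u_older_v) == 1

    def test_empty_set_no_violations(self, fix_a):
        R = cc.resolve([], fix_a)
        assert cc.count_violations(fix_a, R) == 0

    def test_satisfied_constraint_not_counted(self, fix_a):
        R = cc.resolve(
            [
                constraint("c1", ("A", "B"), ("C", "D")),  # violated (10 < 20)
                constraint("c2", ("C", "D"), ("A", "B")),  # satisfied (20 > 10)
            ],
            fix_a,
        )
        assert cc.count_violations(fix_a, R) == 1
        assert cc.violated_ids(fix_a, R) == ["c1"]

    def test_equal_dates_count_satisfied(self, fix_a):
        T = fix_a.copy()
        T.dates[fix_a.mrca(["A", "B"])] = 20.0  # equal to anc(C,D)
        R = cc.resolve([constraint("c1", ("A", "B"), ("C", "D"))], T)
        assert cc.count_violations(T, R) == 0

    def test_tolerance_shields_boundary(self, fix_a, u_older_v):
        T = fix_a.copy()
        T.dates[fix_a.mrca(["A", "B"])] = 20.0 - 1e-9
        assert cc.count_violations(T, u_older_v, tol=1e-6) == 0
        assert cc.count_violations(T, u_older_v, tol=0.0) == 1


class TestDateGaps:
    def test_gap_sign_convention(self, fix_a, u_older_v):
        gaps, mean = cc.date_gaps(fix_a, u_older_v)
        assert gaps["c1"] == pytest.approx(-10.0)  # violated: negative
        assert mean == pytest.approx(-10.0)

    def test_satisfied_gap_positive(self, fix_a):
        R = cc.resolve([constraint("c1", ("C", "D"), ("A", "B"))], fix_a)
        gaps, _ = cc.date_gaps(fix_a, R)
        assert gaps["c1"] == pytest.approx(10.0)

    def test_subset_mean(self, fix_a):
        R = cc.resolve(
            [
                constraint("c1", ("A", "B"), ("C", "D")),
                constraint("c2", ("C", "D"), ("A", "B")),
            ],
            fix_a,
        )
        _, mean = cc.date_gaps(fix_a, R, subset=["c1"])
        assert mean == pytest.approx(-10.0)


def test_topologically_implied_constraint_changes_nothing(fix_a, u_older_v):
    """Adding ancestor-older-than-descendant never changes counts or verdicts."""
    with pytest.warns(RedundantConstraintWarning):
        R2 = cc.resolve(
            [
                constraint("c1", ("A", "B"), ("C", "D")),
                constraint("c3", ("A", "B", "C", "D"), ("A", "B")),  # implied
            ],
            fix_a,
        )
    assert cc.count_violations(fix_a, R2) == cc.count_violations(fix_a, u_older_v)
    assert bool(cc.check_consistency(fix_a, R2)) == bool(
        cc.check_consistency(fix_a, u_older_v)
    )
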