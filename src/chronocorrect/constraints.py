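"""Relative time constraints and their diagnostics.

A relative time constraint asserts that one node of a chronogram is at
least as old as another node that is neither its ancestor nor its
descendant. Such constraints typically come from horizontal gene
transfers: a transfer from donor edge ``(a, b)`` to recipient edge
``(c, d)`` requires the donor and recipient lineages to coexist, so ``a``
(the donor edge's parent) must be older than ``d`` (the recipient edge's
child).

Temporal consistency of a constraint set is decided on the directed graph
whose vertices are the tree nodes, with an edge ``parent -> child`` for
every tree branch and an edge ``older -> younger`` for every constraint:
the system admits a valid dating iff this graph is acyclic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .chronogram import Chronogram, StructureError

__all__ = [
    "NodeRef",
    "RelativeConstraint",
    "ConstraintSet",
    "TransferRecord",
    "ConsistencyReport",
    "RedundantConstraintWarning",
    "resolve",
    "read_constraints",
    "read_transfers",
    "constraint_from_transfer",
    "check_consistency",
    "count_violations",
    "violated_ids",
    "date_gaps",
]


class RedundantConstraintWarning(UserWarning):
    """A constraint whose endpoints are ancestrally related was dropped."""


@dataclass(frozen=True)
class NodeRef:
    """Reference to a tree node: an internal-node label or an MRCA of leaves.

    Text syntax: either a bare internal label, or ``MRCA(tax1;tax2;...)``.
    """

    label: str | None = None
    taxa: tuple[str, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "NodeRef":
        text = text.strip()
        if text.upper().startswith("MRCA(") and text.endswith(")"):
            inner = text[5:-1]
            taxa = tuple(t.strip() for t in inner.split(";") if t.strip())
            if not taxa:
                raise StructureError(f"empty MRCA reference: {text!r}")
            return cls(taxa=taxa)
        if not text:
            raise StructureError("empty node reference")
        return cls(label=text)

    def resolve(self, T: Chronogram) -> int:
        if self.label is not None:
            return T.resolve_label(self.label)
        return T.mrca(list(self.taxa))

    def __str__(self) -> str:
        if self.label is not None:
            return self.label
        return "MRCA(" + ";".join(self.taxa) + ")"


@dataclass(frozen=True)
class TransferRecord:
    """A horizontal transfer, given by the child ends of its two edges."""

    id: str
    donor_edge_child: NodeRef
    recipient_edge_child: NodeRef


@dataclass(frozen=True)
class RelativeConstraint:
    """Assertion that node ``older`` is at least as old as node ``younger``."""

    id: str
    older: NodeRef
    younger: NodeRef
    source: TransferRecord | None = None


@dataclass
class ConstraintSet:
    """Constraints resolved against a fixed topology.

    ``resolved`` maps constraint id -> (older node id, younger node id).
    Node ids refer to the chronogram the set was resolved against; use
    :meth:`remap` to carry the set onto a topology-identical tree.
    """

    constraints: list[RelativeConstraint]
    resolved: dict[str, tuple[int, int]]
    excluded: list[RelativeConstraint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.resolved)

    def __iter__(self):
        return iter(self.resolved.items())

    def pairs(self) -> list[tuple[int, int]]:
        return list(self.resolved.values())

    def remap(self, source: Chronogram, target: Chronogram) -> "ConstraintSet":
        """Re-express node ids against a topology-identical chronogram."""
        src_sets = {i: source.clade_leafset(i) for i in range(1, source.num_nodes + 1)}
        tgt = target.clade_map()
        try:
            resolved = {
                cid: (tgt[src_sets[i]], tgt[src_sets[j]])
                for cid, (i, j) in self.resolved.items()
            }
        except KeyError as exc:
            raise StructureError(
                f"target tree lacks a clade of the source tree: {exc}"
            ) from exc
        return ConstraintSet(list(self.constraints), resolved, list(self.excluded))


@dataclass
class ConsistencyReport:
    consistent: bool
    cycle: list[int] = field(default_factory=list)
    hard: bool = False  # cycle contains a tree edge (not only constraint edges)

    def __bool__(self) -> bool:
        return self.consistent


# ---------------------------------------------------------------------------
# construction


def constraint_from_transfer(rec: TransferRecord, T: Chronogram) -> RelativeConstraint:
    """Derive the relative constraint implied by a transfer.

    A transfer from edge ``(a, b)`` into edge ``(c, d)`` implies that
    ``a = parent(b)`` must be older than ``d``.
    """
    b = rec.donor_edge_child.resolve(T)
    d = rec.recipient_edge_child.resolve(T)
    if b == T.ROOT:
        raise StructureError(
            f"transfer {rec.id}: donor edge child is the root (no donor edge)"
        )
    a = T.parent[b]
    older_ref = (
        NodeRef(label=T.internal_labels[a])
        if a in T.internal_labels
        else NodeRef(taxa=tuple(sorted(T.clade_leafset(a))))
    )
    return RelativeConstraint(
        id=rec.id, older=older_ref, younger=rec.recipient_edge_child, source=rec
    )


def resolve(
    constraints: list[RelativeConstraint], T: Chronogram
) -> ConstraintSet:
    """Resolve constraint node references against a chronogram.

    Constraints whose endpoints are identical or in an ancestor–descendant
    relation are excluded with a :class:`RedundantConstraintWarning`:
    ancestor-older-than-descendant is already implied by the topology, and
    the reverse is topologically impossible.
    """
    ids = [c.id for c in constraints]
    if len(set(ids)) != len(ids):
        raise StructureError("constraint ids must be unique")
    resolved: dict[str, tuple[int, int]] = {}
    excluded: list[RelativeConstraint] = []
    for c in constraints:
        i = c.older.resolve(T)
        j = c.younger.resolve(T)
        if i == j or T.is_ancestor(i, j) or T.is_ancestor(j, i):
            warnings.warn(
                f"constraint {c.id}: nodes {i} and {j} are ancestrally related; "
                "excluded (redundant or topologically impossible)",
                RedundantConstraintWarning,
                stacklevel=2,
            )
            excluded.append(c)
            continue
        resolved[c.id] = (i, j)
    return ConstraintSet(list(constraints), resolved, excluded)


def read_constraints(tsv_text: str) -> list[RelativeConstraint]:
    """Read a constraint TSV with columns ``id``, ``older``, ``younger``."""
    import pandas as pd

    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    need = {"id", "older", "younger"}
    if not need <= set(df.columns):
        raise StructureError(f"constraint TSV must have columns {sorted(need)}")
    return [
        RelativeConstraint(
            id=row["id"],
            older=NodeRef.parse(row["older"]),
            younger=NodeRef.parse(row["younger"]),
        )
        for _, row in df.iterrows()
    ]


def read_transfers(tsv_text: str) -> list[TransferRecord]:
    """Read a transfer TSV with columns ``id``, ``donor_child``, ``recipient_child``."""
    import pandas as pd

    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    need = {"id", "donor_child", "recipient_child"}
    if not need <= set(df.columns):
        raise StructureError(f"transfer TSV must have columns {sorted(need)}")
    return [
        TransferRecord(
            id=row["id"],
            donor_edge_child=NodeRef.parse(row["donor_child"]),
            recipient_edge_child=NodeRef.parse(row["recipient_child"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# diagnostics


def _constraint_graph(T: Chronogram, R: ConstraintSet) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(1, T.num_nodes + 1))
    for child, par in T.parent.items():
        g.add_edge(par, child, kind="tree")
    for _, (i, j) in R:
        g.add_edge(i, j, kind="constraint")
    return g


def check_consistency(T: Chronogram, R: ConstraintSet) -> ConsistencyReport:
    """Decide whether the constraint system admits any valid dating.

    Builds the older-to-younger precedence graph (tree edges plus
    constraint edges) and reports one witnessing directed cycle if any.
    Cycles made only of constraint edges would merely force equal dates,
    but are rejected too; the report's ``hard`` flag distinguishes the two
    cases.
    """
    g = _constraint_graph(T, R)
    try:
        cyc = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:
        return ConsistencyReport(consistent=True)
    nodes = [u for u, v, _ in cyc]
    hard = any(g.edges[u, v]["kind"] == "tree" for u, v, _ in cyc)
    return ConsistencyReport(consistent=False, cycle=nodes, hard=hard)


def violated_ids(T: Chronogram, R: ConstraintSet, tol: float = 0.0) -> list[str]:
    """Ids of constraints ``(i older j)`` with ``t_j - t_i > tol``."""
    return [cid for cid, (i, j) in R if T.dates[j] - T.dates[i] > tol]


def count_violations(T: Chronogram, R: ConstraintSet, tol: float = 0.0) -> int:
    """Number of relative constraints violated by the chronogram's dates."""
    return len(violated_ids(T, R, tol))


def date_gaps(
    T: Chronogram, R: ConstraintSet, subset: list[str] | None = None
) -> tuple[dict[str, float], float]:
    """Per-constraint date gaps ``t_older - t_younger`` and their mean.

    A negative gap means the constraint is violated. If ``subset`` is
    given (e.g. the constraints violated in a reference chronogram), the
    mean is over that subset only.
    """
    gaps = {cid: float(T.dates[i] - T.dates[j]) for cid, (i, j) in R}
    keys = list(gaps) if subset is None else [k for k in subset if k in gaps]
    mean = float("nan") if not keys else sum(gaps[k] for k in keys) / len(keys)
    return gaps, mean
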