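"""Data model and I/O for chronograms (dated rooted binary trees).

A chronogram is a rooted, strictly binary phylogenetic tree in which every
node carries a date, measured backward in time from the tips (so a leaf
sampled today has date 0 and the root carries the largest date).
Equivalently, branch lengths are elapsed time: the length of the branch
above node ``i`` is ``t_parent(i) - t_i``.

Node ids follow a fixed integer convention for a tree with ``n`` leaves:
internal nodes are numbered ``1 .. n-1`` breadth-first from the root
(root = 1) and leaves are numbered ``n .. 2n-1`` in breadth-first order.
These ids are an internal convention; node identity across trees is
established by the set of leaf names below a node (see
:meth:`Chronogram.clade_map`).
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "ChronogramError",
    "StructureError",
    "ConsistencyError",
    "Violation",
    "parse_chronogram",
    "parse_chronograms",
    "write_chronogram",
    "read_leaf_dates",
    "validate",
]


class ChronogramError(ValueError):
    """Base error for malformed chronogram input."""


class StructureError(ChronogramError):
    """Tree is not rooted strictly binary, or references are unresolvable."""


class ConsistencyError(ChronogramError):
    """Branch lengths imply conflicting dates for some internal node."""


@dataclass(frozen=True)
class Violation:
    """One diagnostic record from :func:`validate`."""

    kind: str  # "topology" or "leaf_date"
    node: int
    detail: str


@dataclass
class Chronogram:
    """A dated rooted binary tree.

    Parameters
    ----------
    n : int
        Number of leaves.
    parent : dict[int, int]
        Parent id for every non-root node (ids 2 .. 2n-1).
    dates : numpy.ndarray
        Array of length ``2n`` with ``dates[i]`` the date of node ``i``
        (index 0 unused), in time units (e.g. mya), backward from the tips.
    leaf_names : dict[int, str]
        Taxon name for each leaf id ``n .. 2n-1``.
    internal_labels : dict[int, str]
        Optional Newick labels for internal nodes (may be empty).
    """

    n: int
    parent: dict[int, int]
    dates: np.ndarray
    leaf_names: dict[int, str]
    internal_labels: dict[int, str] = field(default_factory=dict)

    # -- structure ---------------------------------------------------------

    ROOT = 1

    @property
    def num_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def internal_ids(self) -> range:
        return range(1, self.n)

    @property
    def leaf_ids(self) -> range:
        return range(self.n, 2 * self.n)

    @property
    def children(self) -> dict[int, tuple[int, ...]]:
        kids: dict[int, list[int]] = {i: [] for i in self.internal_ids}
        for child, par in self.parent.items():
            kids[par].append(child)
        return {i: tuple(sorted(c)) for i, c in kids.items()}

    def is_leaf(self, i: int) -> bool:
        return i >= self.n

    def branch_length(self, i: int) -> float:
        """Length of the branch above non-root node ``i``."""
        return float(self.dates[self.parent[i]] - self.dates[i])

    def branch_lengths(self) -> dict[int, float]:
        return {i: self.branch_length(i) for i in range(2, self.num_nodes + 1)}

    @property
    def root_age(self) -> float:
        return float(self.dates[self.ROOT])

    def copy(self, dates: np.ndarray | None = None) -> "Chronogram":
        return Chronogram(
            n=self.n,
            parent=dict(self.parent),
            dates=np.array(self.dates if dates is None else dates, dtype=float),
            leaf_names=dict(self.leaf_names),
            internal_labels=dict(self.internal_labels),
        )

    # -- addressing --------------------------------------------------------

    def leaf_id(self, name: str) -> int:
        for i, nm in self.leaf_names.items():
            if nm == name:
                return i
        raise StructureError(f"unknown taxon {name!r}")

    def ancestors(self, i: int) -> list[int]:
        out = []
        while i != self.ROOT:
            i = self.parent[i]
            out.append(i)
        return out

    def is_ancestor(self, a: int, d: int) -> bool:
        """True if ``a`` is a (proper) ancestor of ``d``."""
        return a in self.ancestors(d)

    def mrca(self, names: list[str]) -> int:
        """Most recent common ancestor of a set of leaf names.

        The MRCA of a single leaf is that leaf itself.
        """
        if not names:
            raise StructureError("MRCA of an empty taxon set")
        ids = [self.leaf_id(nm) for nm in names]
        paths = [[i] + self.ancestors(i) for i in ids]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common node = first along any root path
        for node in paths[0]:
            if node in common:
                return node
        raise AssertionError("rooted tree must have a common ancestor")

    def clade_leafset(self, i: int) -> frozenset[str]:
        """Names of the leaves below node ``i`` (``i`` itself if a leaf)."""
        if self.is_leaf(i):
            return frozenset([self.leaf_names[i]])
        out = []
        stack = [i]
        kids = self.children
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(self.leaf_names[v])
            else:
                stack.extend(kids[v])
        return frozenset(out)

    def clade_map(self) -> dict[frozenset[str], int]:
        """Map each clade leaf-name set to its node id.

        This is the node correspondence used across topology-identical
        trees, independent of child ordering in the Newick source.
        """
        return {self.clade_leafset(i): i for i in range(1, self.num_nodes + 1)}

    def resolve_label(self, label: str) -> int:
        for i, lab in self.internal_labels.items():
            if lab == label:
                return i
        raise StructureError(f"unknown internal-node label {label!r}")

    # -- convenience -------------------------------------------------------

    def newick(self, precision: int = 12) -> str:
        return write_chronogram(self, precision=precision)

    def __eq__(self, other: object) -> bool:  # topology + dates
        if not isinstance(other, Chronogram):
            return NotImplemented
        return (
            self.n == other.n
            and self.parent == other.parent
            and self.leaf_names == other.leaf_names
            and np.array_equal(self.dates, other.dates)
        )


# ---------------------------------------------------------------------------
# parsing


def _dendropy_tree(newick_text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise StructureError(f"could not parse Newick: {exc}") from exc


def read_leaf_dates(tsv_text: str) -> dict[str, float]:
    """Parse a leaf-dates table with columns ``taxon`` and ``date``."""
    import pandas as pd

    df = pd.read_csv(io.StringIO(tsv_text), sep="\t")
    if not {"taxon", "date"} <= set(df.columns):
        raise ChronogramError("leaf-dates TSV must have columns 'taxon' and 'date'")
    dates = dict(zip(df["taxon"].astype(str), df["date"].astype(float)))
    if any(d < 0 for d in dates.values()):
        raise ChronogramError("leaf sampling dates must be >= 0")
    return dates


def parse_chronogram(
    newick_text: str,
    leaf_dates: dict[str, float] | None = None,
    rel_tol: float = 1e-6,
) -> Chronogram:
    """Parse a rooted binary Newick string with time-unit branch lengths.

    Node dates are propagated bottom-up from the leaf sampling dates
    (default 0 for every taxon) using the branch lengths. If the two root
    paths of a pair of leaves imply conflicting dates for their common
    ancestor beyond ``rel_tol`` x root age, a :class:`ConsistencyError`
    names the offending node (for contemporary tips this is exactly a
    non-ultrametricity check).

    Raises
    ------
    StructureError
        Non-binary node (polytomy or unifurcation) or unparseable input.
    ChronogramError
        Negative branch length.
    ConsistencyError
        Conflicting implied dates for an internal node.
    """
    tree = _dendropy_tree(newick_text)
    seed = tree.seed_node

    # check binary, collect structure breadth-first
    for nd in tree.preorder_node_iter():
        nch = len(nd.child_nodes())
        if nch not in (0, 2):
            raise StructureError(
                f"non-binary node with {nch} children "
                f"(near {nd.taxon.label if nd.taxon else 'internal node'})"
            )
        if nd is not seed and nd.edge.length is not None and nd.edge.length < 0:
            raise ChronogramError(f"negative branch length {nd.edge.length}")

    leaves = tree.leaf_nodes()
    n = len(leaves)
    if n < 2:
        raise StructureError("a chronogram needs at least 2 leaves")

    # breadth-first id assignment: internal 1..n-1, leaves n..2n-1
    internal_next, leaf_next = 1, n
    ids: dict[dendropy.Node, int] = {}
    queue = deque([seed])
    order = []
    while queue:
        nd = queue.popleft()
        order.append(nd)
        if nd.is_leaf():
            ids[nd] = leaf_next
            leaf_next += 1
        else:
            ids[nd] = internal_next
            internal_next += 1
            queue.extend(nd.child_nodes())

    parent = {ids[nd]: ids[nd.parent_node] for nd in order if nd is not seed}
    leaf_names = {ids[nd]: nd.taxon.label for nd in order if nd.is_leaf()}
    if len(set(leaf_names.values())) != n:
        raise StructureError("duplicate taxon names")
    internal_labels = {
        ids[nd]: nd.label for nd in order if not nd.is_leaf() and nd.label
    }

    if leaf_dates is None:
        leaf_dates = {}
    unknown = set(leaf_dates) - set(leaf_names.values())
    if unknown:
        raise StructureError(f"leaf dates given for unknown taxa: {sorted(unknown)}")

    dates = np.zeros(2 * n, dtype=float)
    for i, nm in leaf_names.items():
        dates[i] = leaf_dates.get(nm, 0.0)

    # bottom-up propagation; postorder guarantees children first
    implied: dict[int, list[float]] = {}
    for nd in tree.postorder_node_iter():
        i = ids[nd]
        if not nd.is_leaf():
            cands = implied[i]
            dates[i] = float(np.mean(cands))
        if nd is not seed:
            bl = nd.edge.length or 0.0
            implied.setdefault(ids[nd.parent_node], []).append(dates[i] + bl)

    scale = max(abs(dates[1]), 1.0)
    for i in range(1, n):
        cands = implied[i]
        if max(cands) - min(cands) > rel_tol * scale:
            raise ConsistencyError(
                f"conflicting implied dates for internal node {i}: "
                f"{min(cands):.6g} vs {max(cands):.6g}"
            )

    return Chronogram(
        n=n,
        parent=parent,
        dates=dates,
        leaf_names=leaf_names,
        internal_labels=internal_labels,
    )


def parse_chronograms(
    multi_newick_text: str,
    leaf_dates: dict[str, float] | None = None,
    rel_tol: float = 1e-6,
) -> list[Chronogram]:
    """Parse a file of Newick trees, one per line (blank lines ignored)."""
    out = []
    for line in multi_newick_text.splitlines():
        line = line.strip()
        if line:
            out.append(parse_chronogram(line, leaf_dates, rel_tol=rel_tol))
    return out


# ---------------------------------------------------------------------------
# writing


def _format_len(x: float, precision: int) -> str:
    s = f"{x:.{precision}g}"
    return s


def write_chronogram(T: Chronogram, precision: int = 12) -> str:
    """Serialize to Newick with branch lengths equal to elapsed time."""
    kids = T.children

    def render(i: int) -> str:
        if T.is_leaf(i):
            body = T.leaf_names[i]
        else:
            parts = ",".join(render(c) for c in kids[i])
            body = f"({parts}){T.internal_labels.get(i, '')}"
        if i == T.ROOT:
            return body
        return f"{body}:{_format_len(T.branch_length(i), precision)}"

    return render(T.ROOT) + ";"


# ---------------------------------------------------------------------------
# validation


def validate(
    T: Chronogram,
    tol: float = 0.0,
    declared_leaf_dates: dict[str, float] | None = None,
) -> list[Violation]:
    """Check the minimal validity conditions of a chronogram.

    Returns an empty list iff every parent is at least as old as each of
    its children (within ``tol``) and every leaf date matches its declared
    sampling date (default 0) within ``tol``.
    """
    out: list[Violation] = []
    for i in range(2, T.num_nodes + 1):
        if T.dates[T.parent[i]] < T.dates[i] - tol:
            out.append(
                Violation(
                    "topology",
                    i,
                    f"node {i} (date {T.dates[i]:.6g}) older than its parent "
                    f"{T.parent[i]} (date {T.dates[T.parent[i]]:.6g})",
                )
            )
    declared = declared_leaf_dates or {}
    for i in T.leaf_ids:
        want = declared.get(T.leaf_names[i], 0.0)
        if abs(T.dates[i] - want) > tol:
            out.append(
                Violation(
                    "leaf_date",
                    i,
                    f"leaf {T.leaf_names[i]!r} dated {T.dates[i]:.6g}, "
                    f"declared {want:.6g}",
                )
            )
    return out
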