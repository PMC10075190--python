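"""Comparison statistics between input, corrected, and baseline chronograms.

All pairwise metrics match nodes by clade leaf-set, so the two trees must
be topology-identical but may come from differently ordered Newick
sources. For a tree with n leaves, node-date deviations average over the
n - 1 internal nodes and branch-length deviations over the 2n - 2 edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chronogram import Chronogram, StructureError
from .constraints import ConstraintSet, count_violations, date_gaps

__all__ = [
    "DEFAULT_HISTOGRAM_EDGES",
    "node_date_deviation",
    "branch_length_deviation",
    "percent_branch_change",
    "percent_change_histogram",
    "deviation_report",
    "model_selection_report",
]

# left-closed, right-open bins; values >= the last edge fall in an overflow bin
DEFAULT_HISTOGRAM_EDGES = (0.0, 1.0, 5.0, 10.0, 20.0, 40.0)


def _matched_dates(A: Chronogram, B: Chronogram) -> tuple[np.ndarray, Chronogram]:
    """B's dates permuted into A's node-id frame."""
    amap, bmap = A.clade_map(), B.clade_map()
    if set(amap) != set(bmap):
        raise StructureError("chronograms are not topology-identical")
    out = np.zeros(A.num_nodes + 1)
    for clade, i in amap.items():
        out[i] = B.dates[bmap[clade]]
    return out, A


def node_date_deviation(A: Chronogram, B: Chronogram) -> float:
    """Mean absolute difference in internal-node dates (symmetric)."""
    bdates, _ = _matched_dates(A, B)
    ids = np.arange(1, A.n)
    return float(np.mean(np.abs(A.dates[ids] - bdates[ids])))


def branch_length_deviation(A: Chronogram, B: Chronogram) -> float:
    """Mean absolute difference in branch lengths over all edges (symmetric)."""
    bdates, _ = _matched_dates(A, B)
    ids = np.arange(2, A.num_nodes + 1)
    par = np.array([A.parent[i] for i in ids])
    ba = A.dates[par] - A.dates[ids]
    bb = bdates[par] - bdates[ids]
    return float(np.mean(np.abs(ba - bb)))


def percent_branch_change(
    A: Chronogram, B: Chronogram, eps_len: float | None = None
) -> tuple[np.ndarray, float]:
    """Per-edge percent change in branch length, input tree A as baseline.

    For the edge above node i: ``|b'_i - b_i| / b_i * 100`` with ``b`` from
    A and ``b'`` from B. Asymmetric by construction — A must be the input
    chronogram. Input lengths are floored at ``eps_len`` (default
    ``1e-8`` x root age) so degenerate zero-length edges do not divide by
    zero.
    """
    if eps_len is None:
        eps_len = 1e-8 * max(A.root_age, 1e-300)
    bdates, _ = _matched_dates(A, B)
    ids = np.arange(2, A.num_nodes + 1)
    par = np.array([A.parent[i] for i in ids])
    ba = A.dates[par] - A.dates[ids]
    bb = bdates[par] - bdates[ids]
    pct = np.abs(bb - ba) / np.maximum(ba, eps_len) * 100.0
    return pct, float(np.mean(pct))


def percent_change_histogram(
    changes: np.ndarray, edges: tuple[float, ...] = DEFAULT_HISTOGRAM_EDGES
) -> tuple[list[str], np.ndarray]:
    """Bin percent changes into left-closed right-open intervals.

    Returns bin labels and counts; the final bin collects everything at or
    above the last edge. Counts sum to the number of values.
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("histogram edges must be strictly increasing")
    changes = np.asarray(changes, dtype=float)
    counts = []
    labels = []
    for lo, hi in zip(edges, edges[1:]):
        counts.append(int(np.sum((changes >= lo) & (changes < hi))))
        labels.append(f"[{lo:g},{hi:g})")
    counts.append(int(np.sum(changes >= edges[-1])))
    labels.append(f"[{edges[-1]:g},inf)")
    return labels, np.asarray(counts)


@dataclass
class DeviationReport:
    violations_input: int
    violations_corrected: int
    node_date_deviation: float
    branch_length_deviation: float
    average_percent_change: float
    percent_changes: np.ndarray
    histogram_labels: list[str]
    histogram_counts: np.ndarray
    average_date_gap_input: float
    average_date_gap_corrected: float
    violated_subset: list[str]

    def to_dict(self) -> dict:
        d = {
            "violations_input": self.violations_input,
            "violations_corrected": self.violations_corrected,
            "node_date_deviation": self.node_date_deviation,
            "branch_length_deviation": self.branch_length_deviation,
            "average_percent_change": self.average_percent_change,
            "average_date_gap_input": self.average_date_gap_input,
            "average_date_gap_corrected": self.average_date_gap_corrected,
        }
        d.update(dict(zip(self.histogram_labels, map(int, self.histogram_counts))))
        return d


def deviation_report(
    input_tree: Chronogram,
    corrected_tree: Chronogram,
    R: ConstraintSet,
    histogram_edges: tuple[float, ...] = DEFAULT_HISTOGRAM_EDGES,
) -> DeviationReport:
    """Full input-vs-corrected comparison.

    The average date gap is computed over the constraints *violated in the
    input tree*, both before and after correction, so the "corrected" gap
    measures how far those formerly violated node pairs were pushed into
    the satisfied region.
    """
    from .constraints import violated_ids

    subset = violated_ids(input_tree, R)
    _, gap_in = date_gaps(input_tree, R, subset=subset)
    R_corr = R.remap(input_tree, corrected_tree)
    _, gap_out = date_gaps(corrected_tree, R_corr, subset=subset)
    pct, avg_pct = percent_branch_change(input_tree, corrected_tree)
    labels, counts = percent_change_histogram(pct, histogram_edges)
    return DeviationReport(
        violations_input=count_violations(input_tree, R),
        violations_corrected=count_violations(corrected_tree, R_corr),
        node_date_deviation=node_date_deviation(input_tree, corrected_tree),
        branch_length_deviation=branch_length_deviation(input_tree, corrected_tree),
        average_percent_change=avg_pct,
        percent_changes=pct,
        histogram_labels=labels,
        histogram_counts=counts,
        average_date_gap_input=gap_in,
        average_date_gap_corrected=gap_out,
        violated_subset=subset,
    )


def model_selection_report(
    inputs: dict[str, tuple[Chronogram, dict[str, Chronogram]]],
    R_by_model: dict[str, ConstraintSet],
    rank_objective: str = "slrb",
    rank_column: str = "node_date_deviation",
) -> pd.DataFrame:
    """Rank candidate dating models by correction effort.

    ``inputs`` maps model name -> (aggregated input chronogram, mapping of
    objective name -> aggregated corrected chronogram); ``R_by_model``
    gives each model's constraint set resolved against its input tree. A
    model whose chronograms need little correction (small deviations,
    small percent change, few violations) is better supported by the
    relative constraints. The ranking is descriptive: rows are sorted
    ascending by ``rank_column`` under ``rank_objective``.
    """
    rows = []
    for model, (agg_in, corrected) in inputs.items():
        R = R_by_model[model]
        for obj, agg_out in corrected.items():
            rep = deviation_report(agg_in, agg_out, R)
            rows.append(
                {
                    "model": model,
                    "objective": obj,
                    "violations_input": rep.violations_input,
                    "node_date_deviation": rep.node_date_deviation,
                    "branch_length_deviation": rep.branch_length_deviation,
                    "average_percent_change": rep.average_percent_change,
                }
            )
    df = pd.DataFrame(rows)
    key = df[df["objective"] == rank_objective].set_index("model")[rank_column]
    df["rank"] = df["model"].map(key.rank(method="min").astype(int))
    return df.sort_values(["rank", "model", "objective"]).reset_index(drop=True)


def render_histogram(labels, counts, path) -> None:
    """Optionally render a percent-change histogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(counts)), counts, tick_label=labels)
    ax.set_xlabel("percent change in branch length")
    ax.set_ylabel("number of edges")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
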