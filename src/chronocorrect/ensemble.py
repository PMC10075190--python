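"""Ensembles of topology-identical chronogram samples.

Posterior samples from a Bayesian dating analysis share one species-tree
topology but differ in node dates. An ensemble matches nodes across
members by the leaf-name set of their clades (robust to child ordering in
the Newick source), aggregates dates into a single representative
chronogram, summarizes per-node date distributions, and implements the
rejection-sampling baseline (keep only samples satisfying at least a
cutoff number of relative constraints).

Aggregation with any monotone summarizer (average, median, min, max)
preserves both topological validity and every relative constraint that
all members satisfy: the aggregated date of an "older" node dominates the
aggregated date of its "younger" partner whenever it does so member-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chronogram import Chronogram, StructureError
from .constraints import ConstraintSet, count_violations

__all__ = [
    "ChronogramEnsemble",
    "AggregateResult",
    "SUMMARIZERS",
    "build_ensemble",
    "aggregate",
    "node_date_distributions",
    "rejection_sample",
    "EmptyEnsembleWarning",
]

SUMMARIZERS = {
    "average": np.mean,
    "median": np.median,
    "min": np.min,
    "max": np.max,
}


class EmptyEnsembleWarning(UserWarning):
    """Rejection sampling removed every member."""


@dataclass
class ChronogramEnsemble:
    """m chronogram samples over one shared topology.

    ``date_matrix`` has shape (m, num_nodes + 1): column ``i`` holds the
    dates of the node whose id is ``i`` *in the reference (first) member*;
    other members' dates are permuted into that frame via the clade map.
    """

    members: list[Chronogram]
    date_matrix: np.ndarray

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def reference(self) -> Chronogram:
        return self.members[0]

    def __len__(self) -> int:
        return self.m


@dataclass
class AggregateResult:
    chronogram: Chronogram
    summarizer: str
    node_means: np.ndarray
    node_sds: np.ndarray
    degenerate_sd: bool = False  # m == 1: sd is 0 by convention
    member_dates: np.ndarray | None = None


def build_ensemble(trees: list[Chronogram]) -> ChronogramEnsemble:
    """Match nodes across topology-identical chronograms.

    Raises :class:`~chronocorrect.chronogram.StructureError` naming the
    first discordant clade if any two members disagree in topology.
    """
    if not trees:
        raise StructureError("ensemble needs at least one chronogram")
    ref = trees[0]
    ref_map = ref.clade_map()
    m = len(trees)
    mat = np.zeros((m, ref.num_nodes + 1))
    mat[0] = ref.dates
    for k, T in enumerate(trees[1:], start=1):
        other = T.clade_map()
        if set(other) != set(ref_map):
            diff = sorted(
                set(other) ^ set(ref_map), key=lambda s: (len(s), sorted(s))
            )[0]
            raise StructureError(
                f"member {k} topology differs from member 0: clade "
                f"{sorted(diff)} is not shared"
            )
        for clade, i in ref_map.items():
            mat[k, i] = T.dates[other[clade]]
    return ChronogramEnsemble(members=list(trees), date_matrix=mat)


def aggregate(
    E: ChronogramEnsemble,
    summarizer: str = "average",
    sd_ddof: int = 1,
) -> AggregateResult:
    """Summarize member dates node-wise into one chronogram."""
    if summarizer not in SUMMARIZERS:
        raise ValueError(f"summarizer must be one of {sorted(SUMMARIZERS)}")
    fn = SUMMARIZERS[summarizer]
    dates = np.zeros(E.reference.num_nodes + 1)
    dates[1:] = fn(E.date_matrix[:, 1:], axis=0)
    agg = E.reference.copy(dates=dates)
    means, sds, degenerate = _moments(E, sd_ddof)
    return AggregateResult(
        chronogram=agg,
        summarizer=summarizer,
        node_means=means,
        node_sds=sds,
        degenerate_sd=degenerate,
        member_dates=E.date_matrix,
    )


def _moments(E: ChronogramEnsemble, sd_ddof: int):
    means = np.zeros(E.reference.num_nodes + 1)
    sds = np.zeros(E.reference.num_nodes + 1)
    means[1:] = E.date_matrix[:, 1:].mean(axis=0)
    degenerate = E.m < 2
    if not degenerate:
        sds[1:] = E.date_matrix[:, 1:].std(axis=0, ddof=sd_ddof)
    return means, sds, degenerate


def node_date_distributions(
    E: ChronogramEnsemble, sd_ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-node (mean, sd) of dates across members, in reference-id frame.

    Sample standard deviation (``ddof=1``) by default. For ``m = 1`` the
    sd is reported as 0 with the degenerate flag set.
    """
    return _moments(E, sd_ddof)


def rejection_sample(
    E: ChronogramEnsemble, R: ConstraintSet, min_satisfied: int
) -> ChronogramEnsemble:
    """Keep members satisfying at least ``min_satisfied`` constraints.

    ``R`` must be resolved against the reference member's topology; each
    member is checked in the reference frame. Member order is preserved.
    Warns and returns an empty ensemble if nothing survives.
    """
    total = len(R)
    keep = []
    for k, T in enumerate(E.members):
        dates = E.date_matrix[k]
        viol = sum(1 for _, (i, j) in R if dates[j] - dates[i] > 0.0)
        if total - viol >= min_satisfied:
            keep.append(k)
    if not keep:
        warnings.warn(
            "rejection sampling removed every member; baseline undefined",
            EmptyEnsembleWarning,
            stacklevel=2,
        )
        return ChronogramEnsemble(members=[], date_matrix=E.date_matrix[:0])
    return ChronogramEnsemble(
        members=[E.members[k] for k in keep], date_matrix=E.date_matrix[keep]
    )


# convenience used by the CLI and tests


def aggregate_violations(
    E: ChronogramEnsemble, R: ConstraintSet, summarizer: str = "average"
) -> int:
    return count_violations(aggregate(E, summarizer).chronogram, R)
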