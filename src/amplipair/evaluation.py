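"""Scoring of taxonomic assignments against ground truth.

Produces per-experiment accuracy tables (per-taxon correct counts), the
per-taxon relative-accuracy weights used by the consensus step (each
taxon's share of the experiment's total correct assignments), accuracies
cumulated at a higher rank (typically phylum), and replicate averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import UNCLASSIFIED
from .taxonomy import Lineage, RANKS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentSpec:
    """Identity of one simulated sequencing experiment."""

    id: str
    target: tuple[str, str]
    read_len: int = 250
    note: str = ""

    def __post_init__(self) -> None:
        if self.target[0] == self.target[1]:
            raise ValueError("target V-regions must differ")


@dataclass
class AccuracyTable:
    """Per-fragment scoring detail for one experiment at one rank.

    ``detail`` has one row per evaluated fragment with columns
    ``fragment_id``, ``truth``, ``assigned``, ``correct``.  Fragments whose
    truth lineage lacks the rank are excluded from the denominator and
    counted in ``n_skipped``.
    """

    experiment: str
    rank: str
    detail: pd.DataFrame
    n_skipped: int = 0

    @property
    def n_evaluated(self) -> int:
        return len(self.detail)

    @property
    def n_correct(self) -> int:
        return int(self.detail["correct"].sum())

    @property
    def n_classified(self) -> int:
        return int((self.detail["assigned"] != UNCLASSIFIED).sum())

    @property
    def accuracy(self) -> float:
        """Headline accuracy: correct / all evaluated (unclassified counts
        as incorrect)."""
        if self.n_evaluated == 0:
            return float("nan")
        return self.n_correct / self.n_evaluated

    @property
    def accuracy_classified(self) -> float:
        """Diagnostic accuracy over fragments that received an assignment."""
        if self.n_classified == 0:
            return float("nan")
        return self.n_correct / self.n_classified

    def correct_by_taxon(self) -> pd.Series:
        """Correct-assignment counts per truth taxon (all truth taxa kept,
        zeros included)."""
        counts = (
            self.detail.groupby("truth", sort=True)["correct"].sum().astype(int)
        )
        return counts

    def summary(self) -> dict:
        return {
            "experiment": self.experiment,
            "rank": self.rank,
            "n_evaluated": self.n_evaluated,
            "n_classified": self.n_classified,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "accuracy_classified": self.accuracy_classified,
        }


def evaluate_assignments(
    assignments: Mapping[str, str],
    truth: Mapping[str, Lineage],
    rank: str,
    experiment: str = "E",
) -> AccuracyTable:
    """Score assignments against truth lineages at one rank.

    A fragment is correct iff its assigned name equals the truth lineage's
    name at *rank*; :data:`UNCLASSIFIED` is never correct.  Assignment and
    truth keys must coincide exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if set(assignments) != set(truth):
        only_a = sorted(set(assignments) - set(truth))[:5]
        only_t = sorted(set(truth) - set(assignments))[:5]
        raise ValueError(
            f"assignment/truth id mismatch (examples: assignments-only {only_a}, "
            f"truth-only {only_t})"
        )
    rows = []
    n_skipped = 0
    for frag_id in assignments:
        true_name = truth[frag_id].name_at(rank)
        if true_name is None:
            n_skipped += 1
            continue
        assigned = assignments[frag_id]
        rows.append(
            {
                "fragment_id": frag_id,
                "truth": true_name,
                "assigned": assigned,
                "correct": assigned != UNCLASSIFIED and assigned == true_name,
            }
        )
    if n_skipped:
        logger.info(
            "%s: %d fragments lacked truth at rank %s and were excluded",
            experiment, n_skipped, rank,
        )
    detail = pd.DataFrame(rows, columns=["fragment_id", "truth", "assigned", "correct"])
    return AccuracyTable(experiment, rank, detail, n_skipped)


def cumulate_by_rank(
    table: AccuracyTable,
    truth: Mapping[str, Lineage],
    group_rank: str = "phylum",
) -> pd.DataFrame:
    """Accuracies grouped at a shallower rank (e.g. species accuracy
    cumulated per phylum).

    Returns a frame indexed by group with columns ``n_evaluated``,
    ``n_correct``, ``accuracy``.  Only observed groups appear.  Group sizes
    reweight exactly to the overall accuracy.
    """
    if group_rank not in RANKS:
        raise ValueError(f"unknown rank {group_rank!r}")
    detail = table.detail.copy()
    detail["group"] = [
        truth[f].name_at(group_rank) for f in detail["fragment_id"]
    ]
    grouped = detail.groupby("group", sort=True).agg(
        n_evaluated=("correct", "size"), n_correct=("correct", "sum")
    )
    grouped["accuracy"] = grouped["n_correct"] / grouped["n_evaluated"]
    return grouped


def compute_weights(table: AccuracyTable) -> dict[str, float]:
    """Per-taxon relative-accuracy weights for one experiment.

    ``W_i = correct_i / total_correct``: each taxon's share of the
    experiment's correct assignments, capturing the target's specificity
    toward the taxon relative to its overall performance.  Weights sum to 1
    across the taxa observed in truth; a taxon never correctly assigned
    gets weight 0.
    """
    total = table.n_correct
    if total == 0:
        raise ValueError(
            f"experiment {table.experiment!r} has no correct assignments; "
            "weights are undefined"
        )
    counts = table.correct_by_taxon()
    return {taxon: count / total for taxon, count in counts.items()}


def average_over_replicates(values: Sequence[float]) -> float:
    """Arithmetic mean over replicate datasets (e.g. five mock datasets per
    gene pool); tabular outputs round it to 2 decimals."""
    if len(values) == 0:
        raise ValueError("no replicate values to average")
    return float(np.mean(values))


def accuracy_matrix(
    tables: Iterable[AccuracyTable],
    truth: Mapping[str, Lineage],
    group_rank: str = "phylum",
) -> pd.DataFrame:
    """Experiments × groups accuracy matrix (heatmap-style summary)."""
    cols = {}
    for table in tables:
        cols[table.experiment] = cumulate_by_rank(table, truth, group_rank)["accuracy"]
    return pd.DataFrame(cols).T
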