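"""High-level study workflows on synthetic references.

Two canned analyses used for validation and reporting:

* a held-out-strain accuracy comparison between single V-regions and a
  non-contiguous V-region pair, and
* a seeded benchmark of the weighted-consensus strategy, measuring how often
  the consensus of two experiments' profiles deviates less from the true
  community composition than the worse single experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .amplicon import (
    RegionMap,
    build_gene_pool,
    dataset_fragments,
    extract_region,
    make_fragment,
    sample_mock_dataset,
)
from .classifier import WordModel, assign_with_threshold, classify_fragments, train
from .consensus import (
    TaxonomicProfile,
    combine_profiles,
    cumulated_deviation,
    normalize_profile,
)
from .evaluation import compute_weights, evaluate_assignments
from .synthref import SyntheticReference
from .taxonomy import ReferenceDB


def heldout_species_accuracy(
    ref: SyntheticReference,
    targets: Sequence[tuple[str, str] | str],
    heldout_suffix: str = "_T3",
    rank: str = "species",
    threshold: float = 0.8,
    read_len: int = 250,
    seed: int = 0,
) -> dict[str, float]:
    """Held-out-strain accuracy per query type.

    Records whose id ends in *heldout_suffix* are excluded from training and
    classified afterwards.  Each entry of *targets* is either a single
    V-region label (the bare extracted region is the query) or a pair
    (a joined 2×*read_len* paired-end fragment is the query).  Returns
    accuracy over all held-out records, keyed e.g. ``"V4"`` or ``"V1+V4"``.
    """
    db = ref.db
    rmap = RegionMap.from_reference(ref)
    train_ids = [r.id for r in db if not r.id.endswith(heldout_suffix)]
    test_ids = [r.id for r in db if r.id.endswith(heldout_suffix)]
    if not test_ids:
        raise ValueError(f"no records end with {heldout_suffix!r}")
    model = train(db.subset(train_ids), rank=rank)
    out: dict[str, float] = {}
    for target in targets:
        if isinstance(target, str):
            key = target
            queries = [(rid, extract_region(db[rid], rmap, target)) for rid in test_ids]
        else:
            key = f"{target[0]}+{target[1]}"
            queries = [
                (rid, make_fragment(db[rid], rmap, target, read_len).sequence)
                for rid in test_ids
            ]
        results = classify_fragments(model, queries, seed=seed)
        correct = sum(
            assign_with_threshold(c, rank, threshold) == db[rid].lineage.name_at(rank)
            for (rid, _), c in zip(queries, results)
        )
        out[key] = correct / len(test_ids)
    return out


def experiment_weights(
    db: ReferenceDB,
    rmap: Mapping,
    model: WordModel,
    target: tuple[str, str],
    rank: str = "species",
    threshold: float = 0.8,
    read_len: int = 250,
    seed: int = 0,
) -> dict[str, float]:
    """Per-taxon relative-accuracy weights for one target, from classifying
    every pool record once (the pre-calculated training evaluation)."""
    frags = [(r.id, make_fragment(r, rmap, target, read_len).sequence) for r in db]
    results = classify_fragments(model, frags, seed=seed)
    assignments = {
        c.fragment_id: assign_with_threshold(c, rank, threshold) for c in results
    }
    truth = {r.id: r.lineage for r in db}
    table = evaluate_assignments(
        assignments, truth, rank, experiment=f"{target[0]}+{target[1]}"
    )
    return compute_weights(table)


def community_truth_profile(community, db: ReferenceDB, rank: str = "species") -> TaxonomicProfile:
    """Expected percent composition of a community at *rank* (each pool
    record equally likely within its taxon)."""
    expected: dict[str, float] = {}
    for taxon, prop in community.proportions.items():
        pool = community.pools[taxon]
        for rid in pool:
            name = db[rid].lineage.name_at(rank)
            expected[name] = expected.get(name, 0.0) + prop / len(pool)
    return normalize_profile(TaxonomicProfile(expected))


@dataclass
class ConsensusTrial:
    seed: int
    deviation_x: float
    deviation_y: float
    deviation_combined: float

    @property
    def improved(self) -> bool:
        return self.deviation_combined < max(self.deviation_x, self.deviation_y)


def consensus_benchmark(
    ref: SyntheticReference,
    target_x: tuple[str, str] = ("V1", "V4"),
    target_y: tuple[str, str] = ("V1", "V5"),
    n_seeds: int = 20,
    n_taxa: int = 6,
    n_reads: int = 300,
    rank: str = "species",
    threshold: float = 0.8,
    seed: int = 0,
) -> list[ConsensusTrial]:
    """Replicated test of the weighted-consensus strategy.

    For each of *n_seeds* random mock communities, two experiments (one per
    target pair) each classify an independent *n_reads*-gene dataset; their
    percent profiles are combined with pre-computed per-taxon weights and
    all three profiles are scored against the community's expected
    composition by cumulated deviation.
    """
    db = ref.db
    rmap = RegionMap.from_reference(ref)
    model = train(db, rank=rank)
    targets = {"x": target_x, "y": target_y}
    weights = {
        key: experiment_weights(db, rmap, model, tgt, rank, threshold, seed=seed)
        for key, tgt in targets.items()
    }
    trials: list[ConsensusTrial] = []
    for s in range(n_seeds):
        community = build_gene_pool(db, n_taxa=n_taxa, rank="genus", seed=seed * 1000 + s)
        truth_profile = community_truth_profile(community, db, rank)
        profiles, deviations = {}, {}
        for i, (key, tgt) in enumerate(targets.items()):
            dataset = sample_mock_dataset(
                community, db, n_reads=n_reads, seed=seed * 1000 + 7 * s + i + 1
            )
            frags = dataset_fragments(dataset, db, rmap, tgt)
            results = classify_fragments(
                model, [(fid, f.sequence) for fid, f in frags], seed=seed
            )
            assigned = [assign_with_threshold(c, rank, threshold) for c in results]
            profiles[key] = normalize_profile(TaxonomicProfile.from_assignments(assigned))
            deviations[key] = cumulated_deviation(profiles[key], truth_profile)
        combined = normalize_profile(
            combine_profiles(profiles["x"], profiles["y"], weights["x"], weights["y"])
        )
        trials.append(
            ConsensusTrial(
                seed=s,
                deviation_x=deviations["x"],
                deviation_y=deviations["y"],
                deviation_combined=cumulated_deviation(combined, truth_profile),
            )
        )
    return trials
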