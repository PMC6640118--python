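"""Amplicon simulation: V-region extraction, paired-end reads, read joining,
and mock-community assembly.

Paired-end protocols sequence a DNA stretch from both ends, so two target
V-regions need not be adjacent: each 250 bp read covers one V-region plus
conserved flanks.  Reads from adjacent targets usually overlap and are
merged into one sequence; reads from distant targets cannot overlap and are
concatenated with eight ``N`` characters, which prevents any 8-mer from
spanning the artificial joint during word-based classification.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synthref import REGION_LABELS, SyntheticReference
from .taxonomy import Lineage, ReferenceDB, ReferenceRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Number of ambiguous bases inserted between non-overlapping read pairs.
#: Equal to the classifier word size, so no word spans the joint.
JOINT_N = 8


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class RegionMap(dict):
    """``record id → region label → (start, end)``, 0-based half-open.

    Regions must appear in gene order (C1 < V1 < … < C10) without overlap.
    """

    @classmethod
    def from_reference(cls, ref: SyntheticReference) -> "RegionMap":
        rmap = cls(ref.regions)
        rmap.validate()
        return rmap

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionMap":
        rmap = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
                rec_id, start, end, label = fields[:4]
                rmap.setdefault(rec_id, {})[label] = (int(start), int(end))
        rmap.validate()
        return rmap

    def validate(self) -> None:
        for rec_id, regions in self.items():
            prev_end = 0
            for lab in REGION_LABELS:
                if lab not in regions:
                    continue
                start, end = regions[lab]
                if not (0 <= start < end):
                    raise ValueError(f"{rec_id}/{lab}: bad interval ({start}, {end})")
                if start < prev_end:
                    raise ValueError(f"{rec_id}/{lab}: regions overlap or out of order")
                prev_end = end


@dataclass(frozen=True)
class ReadPair:
    """A simulated 2×`read_len` read pair targeting V-regions (Va, Vb).

    ``fwd`` is in plus-strand orientation; ``rev`` is as sequenced from the
    minus strand.  The coverage flags report whether each read fully spans
    its target V-region.
    """

    fwd: str
    rev: str
    target: tuple[str, str]
    record_id: str
    read_len: int
    fwd_covers_target: bool
    rev_covers_target: bool


@dataclass(frozen=True)
class Fragment:
    """A joined read pair submitted to classification."""

    sequence: str
    mode: str  # "merged" | "concatenated"
    record_id: str
    target: tuple[str, str]

    def __post_init__(self) -> None:
        if self.mode not in ("merged", "concatenated"):
            raise ValueError(f"unknown join mode {self.mode!r}")


def _region_index(label: str) -> int:
    try:
        return REGION_LABELS.index(label)
    except ValueError:
        raise KeyError(f"unknown region label {label!r}") from None


def parse_target(text: str) -> tuple[str, str]:
    """Parse a target-pair string like ``"V1+V4"`` into ``("V1", "V4")``."""
    parts = text.replace(" ", "").split("+")
    if len(parts) != 2:
        raise ValueError(f"target must name two V-regions, e.g. 'V1+V4'; got {text!r}")
    a, b = parts
    for lab in (a, b):
        if lab not in REGION_LABELS or not lab.startswith("V"):
            raise ValueError(f"{lab!r} is not a V-region label")
    if _region_index(a) >= _region_index(b):
        raise ValueError(f"target pair must be ordered and distinct, got {text!r}")
    return (a, b)


def extract_region(record: ReferenceRecord, region_map: Mapping, label: str) -> str:
    """Sequence of one annotated region of *record* (0-based half-open)."""
    try:
        regions = region_map[record.id]
    except KeyError:
        raise KeyError(f"record {record.id!r} absent from region map") from None
    if label not in regions:
        raise KeyError(f"region {label!r} not mapped for record {record.id!r}")
    start, end = regions[label]
    return record.sequence[start:end]


def simulate_read_pair(
    record: ReferenceRecord,
    region_map: Mapping,
    target: tuple[str, str],
    read_len: int = 250,
) -> ReadPair:
    """Simulate an error-free 2×*read_len* paired-end read for a target pair.

    The forward read is anchored at the start of the conserved region
    immediately upstream of the first target V-region and extends downstream
    up to *read_len* bases; the reverse read is the reverse complement of
    the window ending at the end of the conserved region immediately
    downstream of the second target, extending upstream likewise.  Reads are
    truncated (never padded) at the gene boundaries.
    """
    va, vb = target
    if va == vb:
        raise ValueError("target V-regions must differ")
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    regions = region_map[record.id]
    for lab in (va, vb):
        if lab not in regions:
            raise KeyError(f"region {lab!r} not mapped for record {record.id!r}")
    up_c = f"C{va[1:]}"          # conserved region immediately upstream of Va
    down_c = f"C{int(vb[1:]) + 1}"  # conserved region immediately downstream of Vb
    seq = record.sequence
    f_start = regions[up_c][0]
    f_end = min(f_start + read_len, len(seq))
    r_end = regions[down_c][1]
    r_start = max(r_end - read_len, 0)
    fwd = seq[f_start:f_end]
    rev = revcomp(seq[r_start:r_end])
    return ReadPair(
        fwd=fwd,
        rev=rev,
        target=(va, vb),
        record_id=record.id,
        read_len=read_len,
        fwd_covers_target=f_end >= regions[va][1],
        rev_covers_target=r_start <= regions[vb][0],
    )


def join_read_pair(
    pair: ReadPair, min_overlap: int = 10, max_mismatch_frac: float = 0.1
) -> Fragment:
    """Join a read pair into a single fragment (merge or 8-N concatenation).

    The reverse read is first brought to plus-strand orientation.  Candidate
    overlaps align a forward-read suffix with a reverse-read prefix; among
    overlaps of length >= *min_overlap* with mismatch fraction <=
    *max_mismatch_frac*, the one maximising ``matches − mismatches`` wins
    (longest on ties) and forward-read bases are kept inside the overlap.
    If no acceptable overlap exists the reads are concatenated with exactly
    eight ``N`` characters, preserving orientation.
    """
    fwd = pair.fwd
    rev_plus = revcomp(pair.rev)
    best_len, best_score = 0, None
    max_ov = min(len(fwd), len(rev_plus))
    if max_ov >= min_overlap:
        f_arr = np.frombuffer(fwd.encode("ascii"), dtype=np.uint8)
        r_arr = np.frombuffer(rev_plus.encode("ascii"), dtype=np.uint8)
        for ov in range(min_overlap, max_ov + 1):
            mism = int(np.count_nonzero(f_arr[-ov:] != r_arr[:ov]))
            if mism > max_mismatch_frac * ov:
                continue
            score = ov - 2 * mism
            if (
                best_score is None
                or score > best_score
                or (score == best_score and ov > best_len)
            ):
                best_len, best_score = ov, score
    if best_score is not None:
        seq = fwd + rev_plus[best_len:]
        return Fragment(seq, "merged", pair.record_id, pair.target)
    seq = fwd + "N" * JOINT_N + rev_plus
    return Fragment(seq, "concatenated", pair.record_id, pair.target)


def make_fragment(
    record: ReferenceRecord,
    region_map: Mapping,
    target: tuple[str, str],
    read_len: int = 250,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Fragment:
    """Convenience: simulate a read pair for *target* and join it."""
    pair = simulate_read_pair(record, region_map, target, read_len)
    return join_read_pair(pair, min_overlap, max_mismatch_frac)


# ---------------------------------------------------------------------------
# Mock communities and datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MockCommunity:
    """A pool of reference genes grouped by taxon, with sampling proportions."""

    pools: Mapping[str, tuple[str, ...]]  # taxon -> record ids
    proportions: Mapping[str, float]      # taxon -> fraction (sums to 1)
    rank: str

    def __post_init__(self) -> None:
        if set(self.pools) != set(self.proportions):
            raise ValueError("pools and proportions must cover the same taxa")
        for taxon, ids in self.pools.items():
            if not ids:
                raise ValueError(f"taxon {taxon!r} has an empty gene pool")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.pools)


@dataclass(frozen=True)
class MockDataset:
    """Record ids drawn (with multiplicity) from a community, plus truth."""

    record_ids: tuple[str, ...]
    lineages: tuple[Lineage, ...]
    rank: str

    def __post_init__(self) -> None:
        if len(self.record_ids) != len(self.lineages):
            raise ValueError("record_ids and lineages must align")

    def __len__(self) -> int:
        return len(self.record_ids)

    def truth_at(self, rank: str) -> list[str | None]:
        return [lin.name_at(rank) for lin in self.lineages]


def build_gene_pool(
    db: ReferenceDB, n_taxa: int = 50, rank: str = "genus", seed: int | None = None
) -> MockCommunity:
    """Random mock gene pool: *n_taxa* taxa chosen uniformly without
    replacement, with randomized proportions (flat Dirichlet)."""
    taxa = db.taxa_at(rank)
    if len(taxa) < n_taxa:
        raise ValueError(
            f"database has only {len(taxa)} taxa at rank {rank!r}; need {n_taxa}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(taxa, size=n_taxa, replace=False))
    props = rng.dirichlet(np.ones(n_taxa))
    props = props / props.sum()
    pools = {t: tuple(r.id for r in db.records_for(rank, t)) for t in chosen}
    return MockCommunity(pools, dict(zip(chosen, props.tolist())), rank)


def build_env_community(
    db: ReferenceDB, profile: Mapping[str, float], rank: str = "genus"
) -> MockCommunity:
    """Community whose proportions follow a supplied taxon→abundance profile
    (renormalized), mimicking a known environmental niche."""
    missing = [t for t in profile if t not in db.taxa_at(rank)]
    if missing:
        raise ValueError(f"profile taxa absent from database at rank {rank!r}: {missing}")
    total = float(sum(profile.values()))
    if total <= 0:
        raise ValueError("profile abundances must sum to a positive value")
    pools = {t: tuple(r.id for r in db.records_for(rank, t)) for t in profile}
    props = {t: float(v) / total for t, v in profile.items()}
    return MockCommunity(pools, props, rank)


def load_profile_tsv(path: str | Path) -> dict[str, float]:
    """Read a two-column taxon/abundance TSV (header optional)."""
    profile: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            taxon, _, value = line.partition("\t")
            if lineno == 1:
                try:
                    float(value)
                except ValueError:
                    continue  # header row
            profile[taxon] = float(value)
    return profile


def sample_mock_dataset(
    community: MockCommunity,
    db: ReferenceDB,
    n_reads: int = 10000,
    seed: int | None = None,
) -> MockDataset:
    """Draw *n_reads* genes from a community: taxa per the community
    proportions, then a pool record uniformly within the taxon."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not community.pools:
        raise ValueError("community is empty")
    rng = np.random.default_rng(seed)
    taxa = community.taxa
    probs = np.array([community.proportions[t] for t in taxa])
    taxon_idx = rng.choice(len(taxa), size=n_reads, p=probs)
    ids: list[str] = []
    for ti in taxon_idx:
        pool = community.pools[taxa[ti]]
        ids.append(pool[rng.integers(0, len(pool))])
    lineages = tuple(db[i].lineage for i in ids)
    return MockDataset(tuple(ids), lineages, community.rank)


def dataset_fragments(
    dataset: MockDataset,
    db: ReferenceDB,
    region_map: Mapping,
    target: tuple[str, str],
    read_len: int = 250,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> list[tuple[str, Fragment]]:
    """Fragments for every dataset entry, keyed by a unique fragment id."""
    out = []
    for i, rec_id in enumerate(dataset.record_ids):
        frag = make_fragment(
            db[rec_id], region_map, target, read_len, min_overlap, max_mismatch_frac
        )
        out.append((f"frag{i:06d}_{rec_id}", frag))
    return out


def write_fragments_fasta(
    fragments: Iterable[tuple[str, Fragment]], path: str | Path
) -> None:
    """Write fragments as FASTA with origin/target/mode in the headers."""
    with open(path, "w", encoding="utf-8") as fh:
        for frag_id, frag in fragments:
            fh.write(
                f">{frag_id} origin={frag.record_id} "
                f"target={frag.target[0]}+{frag.target[1]} mode={frag.mode}\n"
            )
            fh.write(frag.sequence + "\n")


def replicate_seed(base_seed: int, pool: int, replicate: int) -> int:
    """Stable per-(pool, replicate) sampling seed below 2**31."""
    return zlib.crc32(f"{base_seed}:{pool}:{replicate}".encode()) % (2**31 - 1)
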