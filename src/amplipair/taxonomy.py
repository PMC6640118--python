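"""Reference-sequence data model: lineages, records and the reference database.

A reference database pairs full-length 16S rRNA gene sequences with
RDP-style lineage annotations (semicolon-delimited rank strings).  Lineages
are positional: the first field is the domain, the last (when present) the
species.  The database derives a taxonomy tree from the lineages and
validates that it is a single-rooted hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical rank order, shallowest first.  Lineages may truncate at any depth.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: IUPAC nucleotide one-letter codes (uppercase).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: Default minimum reference length in bp (near-full-length 16S genes).
DEFAULT_MIN_LENGTH = 1200


class LineageError(ValueError):
    """Raised for malformed lineage strings or unknown rank names."""


@dataclass(frozen=True)
class Lineage:
    """An ordered chain of (rank, taxon-name) pairs from domain downward.

    Parameters
    ----------
    ranks
        Tuple of ``(rank_name, taxon_name)`` pairs.  Ranks must follow the
        canonical order in :data:`RANKS` starting at ``domain``; truncation
        at any depth is allowed.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise LineageError("lineage must contain at least one rank")
        if len(self.ranks) > len(RANKS):
            raise LineageError(
                f"lineage has {len(self.ranks)} ranks; at most {len(RANKS)} allowed"
            )
        for i, (rank, name) in enumerate(self.ranks):
            if rank != RANKS[i]:
                raise LineageError(
                    f"rank {i} is {rank!r}; expected {RANKS[i]!r} (positional order)"
                )
            if not name:
                raise LineageError(f"empty taxon name at rank {rank!r}")

    def name_at(self, rank: str) -> str | None:
        """Taxon name at *rank*, or ``None`` if the lineage truncates above it."""
        if rank not in RANKS:
            raise LineageError(f"unknown rank name {rank!r}")
        idx = RANKS.index(rank)
        if idx >= len(self.ranks):
            return None
        return self.ranks[idx][1]

    def truncated_to(self, rank: str) -> "Lineage":
        """Copy of this lineage cut at *rank* (inclusive)."""
        if rank not in RANKS:
            raise LineageError(f"unknown rank name {rank!r}")
        idx = RANKS.index(rank)
        if idx >= len(self.ranks):
            return self
        return Lineage(self.ranks[: idx + 1])

    @property
    def depth(self) -> int:
        return len(self.ranks)

    @property
    def deepest_rank(self) -> str:
        return self.ranks[-1][0]

    def __str__(self) -> str:
        return ";".join(name for _, name in self.ranks)


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-delimited lineage string into a :class:`Lineage`.

    Fields are assigned to ranks positionally starting at ``domain``.  A
    trailing semicolon is tolerated (common in RDP exports); an empty field
    between separators is a format error.

    >>> str(parse_lineage("Bacteria;Firmicutes"))
    'Bacteria;Firmicutes'
    """
    if not text or not text.strip():
        raise LineageError("empty lineage string")
    stripped = text.strip()
    if stripped.endswith(";"):
        stripped = stripped[:-1]
    fields = [f.strip() for f in stripped.split(";")]
    if any(not f for f in fields):
        raise LineageError(f"empty field in lineage string {text!r}")
    if len(fields) > len(RANKS):
        raise LineageError(
            f"lineage {text!r} has {len(fields)} fields; at most {len(RANKS)} ranks supported"
        )
    return Lineage(tuple(zip(RANKS, fields)))


def lineage_at_rank(lineage: Lineage, rank: str) -> str | None:
    """Functional alias for :meth:`Lineage.name_at`."""
    return lineage.name_at(rank)


@dataclass(frozen=True)
class ReferenceRecord:
    """A full-length reference 16S sequence with its annotated lineage."""

    id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


class TaxonomyError(ValueError):
    """Raised when lineages do not form a single-rooted tree."""


class ReferenceDB:
    """A collection of reference records plus the taxonomy tree they induce.

    The tree is stored as a child → parent map over ``(rank, name)`` nodes.
    Construction fails if two lineages disagree on a taxon's parent or if the
    records do not share a single domain-level root.
    """

    def __init__(self, records: Iterable[ReferenceRecord]):
        self._records: dict[str, ReferenceRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise ValueError(f"duplicate record id {rec.id!r}")
            self._records[rec.id] = rec
        self._parent: dict[tuple[str, str], tuple[str, str] | None] = {}
        self._build_tree()

    def _build_tree(self) -> None:
        roots: set[str] = set()
        for rec in self._records.values():
            prev: tuple[str, str] | None = None
            for rank, name in rec.lineage.ranks:
                node = (rank, name)
                if node in self._parent and self._parent[node] != prev:
                    raise TaxonomyError(
                        f"taxon {name!r} at rank {rank!r} has conflicting parents "
                        f"{self._parent[node]!r} and {prev!r}"
                    )
                self._parent[node] = prev
                prev = node
            roots.add(rec.lineage.ranks[0][1])
        if len(roots) > 1:
            raise TaxonomyError(f"multiple domain-level roots: {sorted(roots)!r}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self._records.values())

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def __getitem__(self, record_id: str) -> ReferenceRecord:
        return self._records[record_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    # -- taxonomy queries ---------------------------------------------------
    def taxa_at(self, rank: str) -> list[str]:
        """Sorted distinct taxon names observed at *rank*."""
        if rank not in RANKS:
            raise LineageError(f"unknown rank name {rank!r}")
        return sorted({n for (r, n) in self._parent if r == rank})

    def records_for(self, rank: str, name: str) -> list[ReferenceRecord]:
        """All records whose lineage carries *name* at *rank*."""
        return [r for r in self if r.lineage.name_at(rank) == name]

    def subset(self, record_ids: Iterable[str]) -> "ReferenceDB":
        return ReferenceDB(self._records[i] for i in record_ids)

    def parent_of(self, rank: str, name: str) -> tuple[str, str] | None:
        return self._parent[(rank, name)]


def load_reference(
    seq_path: str | Path,
    tax_path: str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> ReferenceDB:
    """Load a reference database from a FASTA file and a lineage TSV.

    The lineage file has two tab-separated columns: record id and the
    semicolon-delimited lineage.  Records shorter than *min_length* are
    dropped (the count is logged); a FASTA id missing from the lineage file
    is an error.

    Returns
    -------
    ReferenceDB
        Records passing the length filter, with the derived taxonomy tree.
    """
    lineages: dict[str, Lineage] = {}
    with open(tax_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{tax_path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rec_id, lineage_text = parts
            lineages[rec_id] = parse_lineage(lineage_text)

    records: list[ReferenceRecord] = []
    missing: list[str] = []
    n_short = 0
    n_total = 0
    for seq_rec in SeqIO.parse(str(seq_path), "fasta"):
        n_total += 1
        if seq_rec.id not in lineages:
            missing.append(seq_rec.id)
            continue
        if len(seq_rec.seq) < min_length:
            n_short += 1
            continue
        records.append(
            ReferenceRecord(seq_rec.id, str(seq_rec.seq), lineages[seq_rec.id])
        )
    if missing:
        raise ValueError(
            f"FASTA ids missing from taxonomy file {tax_path}: {missing!r}"
        )
    if n_short:
        logger.info("dropped %d/%d records shorter than %d bp", n_short, n_total, min_length)
    if not records:
        logger.warning("reference %s yielded no records after filtering", seq_path)
    return ReferenceDB(records)
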