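"""Synthetic 16S-like reference generator.

Real 16S rRNA genes interleave nine hypervariable regions (V1–V9) with ten
conserved regions (C1–C10); variable regions accumulate substitutions much
faster than conserved ones, which is what word-based classifiers exploit.
This module evolves a hierarchy of sequences (phyla → genera → species →
strains) down from a random root so that divergence grows with taxonomic
distance, and records exact ground-truth region coordinates and lineages for
every record.  The output stands in for a curated reference download and is
written as FASTA + lineage TSV + BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .taxonomy import Lineage, RANKS, ReferenceDB, ReferenceRecord

logger = logging.getLogger(__name__)

#: Region labels in gene order: C1, V1, C2, V2, …, V9, C10.
REGION_LABELS: tuple[str, ...] = tuple(
    lab for i in range(1, 10) for lab in (f"C{i}", f"V{i}")
) + ("C10",)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Default per-region lengths (bp).  Chosen so the multi-region spans match
# typical amplicon lengths: V2..V3 = 297, V3..V4 = 254, V2..V4 = 482,
# V4..V6 = 453, total 1,500.
DEFAULT_REGION_LENGTHS: dict[str, int] = {
    "C1": 28, "V1": 70, "C2": 60, "V2": 189, "C3": 39, "V3": 69,
    "C4": 70, "V4": 115, "C5": 80, "V5": 60, "C6": 90, "V6": 108,
    "C7": 55, "V7": 80, "C8": 45, "V8": 95, "C9": 55, "V9": 90,
    "C10": 102,
}

_PRESETS: dict[str, Mapping[str, int]] = {"default": DEFAULT_REGION_LENGTHS}


@dataclass(frozen=True)
class RegionTemplate:
    """Ordered (label, length) specs for the 19 alternating C/V regions."""

    regions: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        labels = tuple(lab for lab, _ in self.regions)
        if labels != REGION_LABELS:
            raise ValueError(
                f"template must list the 19 regions {REGION_LABELS} in order; got {labels}"
            )
        for lab, length in self.regions:
            if length <= 0:
                raise ValueError(f"region {lab} has non-positive length {length}")

    def length_of(self, label: str) -> int:
        for lab, length in self.regions:
            if lab == label:
                return length
        raise KeyError(label)

    def span(self, first: str, last: str) -> int:
        """Total length of the inclusive region stretch *first*..*last*."""
        labels = [lab for lab, _ in self.regions]
        i, j = labels.index(first), labels.index(last)
        if i > j:
            raise ValueError(f"{first} does not precede {last}")
        return sum(length for _, length in self.regions[i : j + 1])

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.regions)


def build_template(
    lengths: Mapping[str, int] | None = None, preset: str = "default"
) -> RegionTemplate:
    """Build a :class:`RegionTemplate` from explicit lengths or a named preset.

    With no arguments, the ``default`` preset is used (1,500 bp total, see
    :data:`DEFAULT_REGION_LENGTHS`).  Explicit *lengths* must cover all 19
    region labels.
    """
    if lengths is None:
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; available: {sorted(_PRESETS)}")
        lengths = _PRESETS[preset]
    missing = set(REGION_LABELS) - set(lengths)
    extra = set(lengths) - set(REGION_LABELS)
    if missing or extra:
        raise ValueError(
            f"lengths must specify exactly the 19 region labels; "
            f"missing={sorted(missing)} extra={sorted(extra)}"
        )
    return RegionTemplate(tuple((lab, int(lengths[lab])) for lab in REGION_LABELS))


@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the hierarchical divergence model.

    Rates are per-site substitution probabilities applied at each split of
    the hierarchy, one pair (conserved, variable) per level.  Levels are
    ordered root→phylum, phylum→genus, genus→species, species→strain.
    Indels are applied per variable region with probability ``indel_prob``
    and length 1..``max_indel``; conserved regions stay indel-free so that
    read anchors remain comparable across records.
    """

    n_phyla: int = 2
    n_genera: int = 5
    n_species: int = 3
    n_strains: int = 3
    conserved_rates: tuple[float, float, float, float] = (0.04, 0.02, 0.01, 0.005)
    variable_rates: tuple[float, float, float, float] = (0.20, 0.12, 0.06, 0.02)
    indel_prob: float = 0.05
    max_indel: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for n, what in [
            (self.n_phyla, "n_phyla"), (self.n_genera, "n_genera"),
            (self.n_species, "n_species"), (self.n_strains, "n_strains"),
        ]:
            if n <= 0:
                raise ValueError(f"{what} must be positive, got {n}")
        for c, v in zip(self.conserved_rates, self.variable_rates):
            if not (0.0 <= c <= 1.0 and 0.0 <= v <= 1.0):
                raise ValueError("substitution rates must lie in [0, 1]")
            if v < c:
                raise ValueError(
                    "variable-region rate must be >= conserved-region rate at every level"
                )
        if not 0.0 <= self.indel_prob <= 1.0:
            raise ValueError("indel_prob must lie in [0, 1]")
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")


@dataclass
class SyntheticReference:
    """A generated reference database plus ground-truth region coordinates."""

    db: ReferenceDB
    regions: dict[str, dict[str, tuple[int, int]]]

    def __post_init__(self) -> None:
        for rec in self.db:
            rmap = self.regions.get(rec.id)
            if rmap is None or set(rmap) != set(REGION_LABELS):
                raise ValueError(f"record {rec.id!r} lacks a full 19-region map")
            if rmap["C10"][1] != len(rec.sequence):
                raise ValueError(f"record {rec.id!r}: region map inconsistent with length")


def _mutate_region(
    region: np.ndarray, rate: float, rng: np.random.Generator,
    indel_prob: float = 0.0, max_indel: int = 0,
) -> np.ndarray:
    """Per-site substitution to a uniformly random different base, plus at
    most one short indel (insert or delete) at a random position."""
    out = region.copy()
    hits = np.nonzero(rng.random(out.size) < rate)[0]
    if hits.size:
        # shift by 1..3 in base space => always a different base
        codes = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(codes + rng.integers(1, 4, hits.size)) % 4]
    if indel_prob and rng.random() < indel_prob:
        ln = int(rng.integers(1, max_indel + 1))
        if rng.random() < 0.5 and out.size > ln + 1:  # deletion
            pos = int(rng.integers(0, out.size - ln))
            out = np.delete(out, slice(pos, pos + ln))
        else:  # insertion
            pos = int(rng.integers(0, out.size + 1))
            out = np.insert(out, pos, _BASES[rng.integers(0, 4, ln)])
    return out


def evolve_reference(
    template: RegionTemplate, params: EvolutionParams
) -> SyntheticReference:
    """Evolve a reference hierarchy down from a random root sequence.

    Each taxonomic split mutates every region of the parent sequence with
    the level's (conserved, variable) substitution rates, so expected
    pairwise divergence within any variable region grows with taxonomic
    distance.  Output is deterministic for a given ``params.seed``.

    Returns ``n_phyla × n_genera × n_species × n_strains`` records with
    systematic lineages (phylum ``P01``…, genus ``G001``…, species
    ``S001``…) and exact post-indel region coordinates.
    """
    rng = np.random.default_rng(params.seed)
    root = {
        lab: _BASES[rng.integers(0, 4, length)]
        for lab, length in template.regions
    }

    def split(parent: dict[str, np.ndarray], level: int) -> dict[str, np.ndarray]:
        child = {}
        for lab, region in parent.items():
            if lab.startswith("V"):
                child[lab] = _mutate_region(
                    region, params.variable_rates[level], rng,
                    params.indel_prob, params.max_indel,
                )
            else:
                child[lab] = _mutate_region(region, params.conserved_rates[level], rng)
        return child

    records: list[ReferenceRecord] = []
    regions: dict[str, dict[str, tuple[int, int]]] = {}
    genus_no = species_no = 0
    for p in range(params.n_phyla):
        phylum = split(root, 0)
        p_name = f"P{p + 1:02d}"
        upper = (p_name, f"C{p + 1:02d}", f"O{p + 1:02d}", f"F{p + 1:02d}")
        for _ in range(params.n_genera):
            genus_no += 1
            genus = split(phylum, 1)
            g_name = f"G{genus_no:03d}"
            for _ in range(params.n_species):
                species_no += 1
                species = split(genus, 2)
                s_name = f"S{species_no:03d}"
                lineage = Lineage(tuple(zip(RANKS, ("Bacteria",) + upper + (g_name, s_name))))
                for t in range(params.n_strains):
                    strain = split(species, 3)
                    rec_id = f"{g_name}_{s_name}_T{t + 1}"
                    seq_parts, rmap, pos = [], {}, 0
                    for lab, _ in template.regions:
                        arr = strain[lab]
                        rmap[lab] = (pos, pos + arr.size)
                        pos += arr.size
                        seq_parts.append(arr.tobytes().decode("ascii"))
                    records.append(ReferenceRecord(rec_id, "".join(seq_parts), lineage))
                    regions[rec_id] = rmap
    return SyntheticReference(ReferenceDB(records), regions)


def write_reference(ref: SyntheticReference, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic reference as FASTA, lineage TSV and region BED.

    BED rows are ``record<TAB>start<TAB>end<TAB>label`` with 0-based
    half-open coordinates.  Returns the paths keyed ``fasta``, ``taxonomy``,
    ``bed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "reference.fasta",
        "taxonomy": out / "reference.tax.tsv",
        "bed": out / "reference.regions.bed",
    }
    if len(ref.db) == 0:
        logger.warning("writing empty reference to %s", out)
    with open(paths["fasta"], "w", encoding="utf-8") as fa, open(
        paths["taxonomy"], "w", encoding="utf-8"
    ) as tx, open(paths["bed"], "w", encoding="utf-8") as bed:
        for rec in ref.db:
            fa.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 80):
                fa.write(rec.sequence[i : i + 80] + "\n")
            tx.write(f"{rec.id}\t{rec.lineage}\n")
            for lab in REGION_LABELS:
                start, end = ref.regions[rec.id][lab]
                bed.write(f"{rec.id}\t{start}\t{end}\t{lab}\n")
    return paths
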