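"""Word-based naive-Bayes taxonomic classifier with bootstrap confidence.

The classifier scores a query by the joint probability of its distinct
8-mer words under each training taxon, following the well-known
naive-Bayes algorithm used inside the RDP classifier:

* word prior      ``P(w)   = (n(w) + 0.5) / (N + 1)``
* word likelihood ``P(w|t) = (m(w, t) + P(w)) / (M_t + 1)``

where ``n(w)`` counts training sequences containing ``w`` (out of ``N``)
and ``m(w, t)`` counts sequences of taxon ``t`` containing ``w`` (out of
``M_t``).  A query is assigned to the taxon maximising ``Σ log P(w|t)``
over its distinct valid words; confidence comes from 100 bootstrap trials,
each scoring a resample of one eighth of the query words.  Windows that
contain any ambiguous base are skipped, so the 8-N joint inserted between
concatenated paired-end reads never produces spurious words.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .taxonomy import Lineage, RANKS, ReferenceDB, parse_lineage

#: Default word size; matches the 8-mer vocabulary of the RDP classifier.
DEFAULT_K = 8

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _window_codes(sequence: str, k: int) -> np.ndarray:
    """Integer codes of all k-length windows made only of A/C/G/T.

    Windows touching any other character (ambiguity codes, the 8-N joint)
    are dropped — the guard against spurious words bridging concatenated
    reads.
    """
    codes = _CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid] @ weights


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def extract_words(sequence: str, k: int = DEFAULT_K) -> list[str]:
    """All k-words of *sequence* (multiset, in order), skipping any window
    that contains a non-A/C/G/T character.

    >>> extract_words("ACGTACGTA")
    ['ACGTACGT', 'CGTACGTA']
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return [_decode(int(c), k) for c in _window_codes(sequence, k)]


@dataclass
class WordModel:
    """Trained word model: vocabulary, log-likelihood matrix and taxon list.

    ``log_cond[t, j]`` is ``log P(vocab[j] | taxa[t])``; ``log_unseen[t]``
    is the per-taxon log-likelihood of any word never seen in training
    (``log(0.5/(N+1)) − log(M_t+1)``).  Taxa are sorted lexicographically,
    which makes ``argmax`` tie-breaking deterministic.
    """

    k: int
    rank: str
    taxa: list[str]
    lineages: list[Lineage]
    vocab: np.ndarray          # sorted distinct word codes, shape (V,)
    log_cond: np.ndarray       # shape (T, V)
    log_unseen: np.ndarray     # shape (T,)
    n_train: int
    taxon_counts: np.ndarray   # M_t per taxon, shape (T,)

    def save(self, path: str | Path) -> None:
        """Serialize the model to a single ``.npz`` archive."""
        np.savez_compressed(
            path,
            k=self.k,
            rank=self.rank,
            taxa=np.array(self.taxa),
            lineages=np.array([str(l) for l in self.lineages]),
            vocab=self.vocab,
            log_cond=self.log_cond,
            log_unseen=self.log_unseen,
            n_train=self.n_train,
            taxon_counts=self.taxon_counts,
        )

    @classmethod
    def load(cls, path: str | Path) -> "WordModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                k=int(z["k"]),
                rank=str(z["rank"]),
                taxa=[str(t) for t in z["taxa"]],
                lineages=[parse_lineage(str(l)) for l in z["lineages"]],
                vocab=z["vocab"],
                log_cond=z["log_cond"],
                log_unseen=z["log_unseen"],
                n_train=int(z["n_train"]),
                taxon_counts=z["taxon_counts"],
            )


@dataclass(frozen=True)
class Classification:
    """Per-rank assignments with bootstrap confidences for one query.

    ``assignments`` maps each rank of the winning taxon's lineage to
    ``(taxon name, confidence)``; shallower assignments are by construction
    ancestors of the winner.  ``classifiable`` is False when the query
    yields no valid word.
    """

    fragment_id: str
    classifiable: bool
    winner: str | None
    assignments: Mapping[str, tuple[str, float]]

    def confidence_at(self, rank: str) -> float:
        if rank not in self.assignments:
            return 0.0
        return self.assignments[rank][1]


UNCLASSIFIED = "unclassified"


def train(db: ReferenceDB, k: int = DEFAULT_K, rank: str = "species") -> WordModel:
    """Train a word model on a reference database at the given rank.

    Every record must carry a name at *rank*.  Word counts use presence per
    training sequence (not multiplicity).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    by_taxon: dict[str, list] = {}
    lineage_of: dict[str, Lineage] = {}
    for rec in db:
        name = rec.lineage.name_at(rank)
        if name is None:
            raise ValueError(f"record {rec.id!r} has no name at rank {rank!r}")
        by_taxon.setdefault(name, []).append(rec)
        lineage_of.setdefault(name, rec.lineage.truncated_to(rank))
    taxa = sorted(by_taxon)

    seq_words = []  # per training sequence: unique word codes
    for t in taxa:
        for rec in by_taxon[t]:
            seq_words.append(np.unique(_window_codes(rec.sequence, k)))
    n_train = len(seq_words)
    vocab = np.unique(np.concatenate(seq_words)) if seq_words else np.empty(0, np.int64)

    # n(w): number of training sequences containing w
    n_w = np.zeros(vocab.size, dtype=np.int64)
    per_seq_idx = []
    for words in seq_words:
        idx = np.searchsorted(vocab, words)
        n_w[idx] += 1
        per_seq_idx.append(idx)
    prior = (n_w + 0.5) / (n_train + 1)

    log_cond = np.empty((len(taxa), vocab.size))
    taxon_counts = np.empty(len(taxa), dtype=np.int64)
    pos = 0
    for ti, t in enumerate(taxa):
        m_t = len(by_taxon[t])
        taxon_counts[ti] = m_t
        m_w = np.zeros(vocab.size, dtype=np.int64)
        for idx in per_seq_idx[pos : pos + m_t]:
            m_w[idx] += 1
        pos += m_t
        log_cond[ti] = np.log((m_w + prior) / (m_t + 1))
    log_unseen = math.log(0.5 / (n_train + 1)) - np.log(taxon_counts + 1.0)
    return WordModel(
        k=k,
        rank=rank,
        taxa=taxa,
        lineages=[lineage_of[t] for t in taxa],
        vocab=vocab,
        log_cond=log_cond,
        log_unseen=log_unseen,
        n_train=n_train,
        taxon_counts=taxon_counts,
    )


def _fragment_rng(fragment_id: str, seed: int) -> np.random.Generator:
    # per-fragment stream: results do not depend on classification order
    return np.random.default_rng([seed, zlib.crc32(fragment_id.encode())])


def classify(
    model: WordModel,
    sequence: str,
    fragment_id: str = "query",
    n_bootstrap: int = 100,
    seed: int = 0,
) -> Classification:
    """Classify one fragment and estimate per-rank bootstrap confidence.

    The full-query winner maximises the summed log-likelihood of the
    query's distinct words.  Each bootstrap trial resamples ``ceil(U/8)``
    of the ``U`` distinct words with replacement and records its own
    winner; the confidence at a rank is the fraction of trials agreeing
    with the full-query winner's lineage at that rank.  Results are
    deterministic given ``(fragment_id, seed)``.
    """
    words = np.unique(_window_codes(sequence, model.k))
    if words.size == 0:
        return Classification(fragment_id, False, None, {})
    idx = np.searchsorted(model.vocab, words)
    idx = np.clip(idx, 0, max(model.vocab.size - 1, 0))
    seen = model.vocab.size > 0 and (model.vocab[idx] == words)
    if model.vocab.size == 0:
        seen = np.zeros(words.size, dtype=bool)

    # per-word per-taxon log-likelihood contributions, shape (T, U)
    contrib = np.empty((len(model.taxa), words.size))
    if seen.any():
        contrib[:, seen] = model.log_cond[:, idx[seen]]
    if (~seen).any():
        contrib[:, ~seen] = model.log_unseen[:, None]

    scores = contrib.sum(axis=1)
    win_t = int(np.argmax(scores))  # taxa sorted => lexicographic tie-break
    winner = model.taxa[win_t]
    win_lineage = model.lineages[win_t]

    u = words.size
    n_sub = max(1, math.ceil(u / 8))
    rng = _fragment_rng(fragment_id, seed)
    samples = rng.integers(0, u, size=(n_bootstrap, n_sub))
    trial_scores = contrib[:, samples].sum(axis=2)        # (T, n_bootstrap)
    trial_winners = np.argmax(trial_scores, axis=0)

    lineage_names = [l.ranks for l in model.lineages]
    assignments: dict[str, tuple[str, float]] = {}
    for ri, (rank, name) in enumerate(win_lineage.ranks):
        agree = sum(
            1
            for tw in trial_winners
            if ri < len(lineage_names[tw]) and lineage_names[tw][ri][1] == name
        )
        assignments[rank] = (name, agree / n_bootstrap)
    return Classification(fragment_id, True, winner, assignments)


def assign_with_threshold(
    cls: Classification, rank: str, threshold: float = 0.8
) -> str:
    """The assignment at *rank* if its confidence is >= *threshold*
    (inclusive), else :data:`UNCLASSIFIED`."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if not cls.classifiable or rank not in cls.assignments:
        return UNCLASSIFIED
    name, conf = cls.assignments[rank]
    return name if conf >= threshold else UNCLASSIFIED


def classify_fragments(
    model: WordModel,
    fragments: Iterable[tuple[str, str]],
    n_bootstrap: int = 100,
    seed: int = 0,
) -> list[Classification]:
    """Classify ``(fragment_id, sequence)`` pairs; order-independent."""
    return [
        classify(model, seq, frag_id, n_bootstrap=n_bootstrap, seed=seed)
        for frag_id, seq in fragments
    ]


def classifications_to_rows(
    classifications: Iterable[Classification], threshold: float = 0.8
) -> list[dict]:
    """Flatten classifications into TSV-ready rows (one per fragment)."""
    rows = []
    for c in classifications:
        row: dict = {"fragment_id": c.fragment_id, "classifiable": c.classifiable}
        for rank in RANKS:
            if rank in c.assignments:
                name, conf = c.assignments[rank]
                row[f"{rank}"] = name
                row[f"{rank}_confidence"] = conf
                row[f"{rank}_assigned"] = name if conf >= threshold else UNCLASSIFIED
        rows.append(row)
    return rows
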