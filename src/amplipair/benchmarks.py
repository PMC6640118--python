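"""Bundled benchmark tables.

Two small published evaluation tables ship with the package as TSV:

* ``gut_profile_benchmark.tsv`` — species-level percent-abundance profiles
  of a simulated human-gut community (50 species) estimated from
  full-length 16S genes, from paired-end fragments targeting V1+V4 and
  V1+V5, and from the weighted consensus of the two targets.
* ``mock_pool_accuracies.tsv`` — species-level classification accuracies of
  twenty V-region targets on mock communities drawn from five random
  50-genus gene pools (five replicate datasets of 10,000 genes each).

They serve as fixed inputs for the deviation metric and replicate-averaging
utilities and as worked examples in the documentation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .consensus import PERCENT, TaxonomicProfile


def _read(name: str) -> pd.DataFrame:
    with resources.files("amplipair.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_gut_profiles() -> pd.DataFrame:
    """The gut-community benchmark profiles, indexed by species."""
    return _read("gut_profile_benchmark.tsv").set_index("species")


def gut_profile(column: str) -> TaxonomicProfile:
    """One column of the gut benchmark as a percent profile.

    Columns: ``full_length``, ``v1_v4``, ``v1_v5``, ``combined``.
    """
    frame = load_gut_profiles()
    if column not in frame.columns:
        raise KeyError(f"unknown profile column {column!r}; have {list(frame.columns)}")
    return TaxonomicProfile(frame[column].to_dict(), PERCENT)


def load_pool_accuracies() -> pd.DataFrame:
    """The mock-pool accuracy benchmark, indexed by V-region combination."""
    return _read("mock_pool_accuracies.tsv").set_index("combination")
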