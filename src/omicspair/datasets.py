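"""Bundled worked-example candidate-pair tables.

Two small published result tables from a two-breed pig feed-efficiency
study ship with the package as plain TSV: one breed-contrast table
(21 pairs, group0 = Duroc, group1 = Landrace) and one feed-efficiency
contrast table (12 pairs, group0 = high FE, group1 = low FE).  They
carry per-group Spearman correlations, interaction p-values and FDR
values, and serve as deterministic fixtures for the significance
filter, the correlation-difference convention, and sign clustering.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .integrate import correlation_difference


def _load(name: str) -> pd.DataFrame:
    with resources.files("omicspair.data").joinpath(name).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    df["diff_corr"] = [correlation_difference(c0, c1)
                       for c0, c1 in zip(df["cor_group0"], df["cor_group1"])]
    df["abs_diff_corr"] = df["diff_corr"].abs()
    df["significant"] = False
    df["cluster"] = "none"
    return df


def example_breed_pairs() -> pd.DataFrame:
    """21 breed-contrast pairs; group0 is Duroc, group1 is Landrace."""
    return _load("example_pairs_breed.tsv")


def example_fe_pairs() -> pd.DataFrame:
    """12 feed-efficiency pairs; group0 is high FE, group1 is low FE."""
    return _load("example_pairs_fe.tsv")
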