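"""Overlap enrichment of discrete gene lists against gene-set collections
(hypergeometric) and pairwise list-overlap testing (Fisher's exact).

The universe size is a mandatory explicit argument — a sensible choice is
the number of genes measured on the platform for list-vs-list tests, or the
collection universe for collection-style tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from factorde.stats import (
    Overlap2x2,
    bh_adjust,
    fisher_exact_overlap,
    hypergeom_upper_tail,
)
from factorde.types import GeneSetCollection


def _folded_unique(genes: list[str], name: str) -> set[str]:
    folded = [g.casefold() for g in genes]
    if len(set(folded)) != len(folded):
        dupes = sorted({g for g in folded if folded.count(g) > 1})
        raise ValueError(f"{name} contains duplicate gene(s): {dupes[:5]}")
    return set(folded)


def enrich_list(
    query: list[str],
    collection: GeneSetCollection,
    universe_size: int,
) -> pd.DataFrame:
    """Hypergeometric overlap of a query gene list with every set.

    When the collection declares a universe, both members and the query are
    restricted to it; sets empty after restriction are dropped. Rows sorted
    by q ascending, then set name. Columns: genes_in_set (K),
    genes_in_overlap (k), p, q.
    """
    q_folded = _folded_unique(query, "query")
    universe_folded: set[str] | None = None
    if collection.universe is not None:
        universe_folded = {g.casefold() for g in collection.universe}
        q_folded = q_folded & universe_folded
    if universe_size < len(q_folded):
        raise ValueError(
            f"universe_size ({universe_size}) smaller than the (restricted) "
            f"query ({len(q_folded)})"
        )
    rows = []
    for name in collection.names:
        members = collection.members_folded(name)
        if universe_folded is not None:
            members = members & universe_folded
        K = len(members)
        if K == 0:
            continue  # sets unrepresented in the universe are not tested
        if universe_size < K:
            raise ValueError(
                f"universe_size ({universe_size}) smaller than set "
                f"{name!r} ({K} genes)"
            )
        k = len(members & q_folded)
        p = hypergeom_upper_tail(Overlap2x2(k=k, K=K, n=len(q_folded), N=universe_size))
        rows.append((name, K, k, p))
    if not rows:
        return pd.DataFrame(
            columns=["genes_in_set", "genes_in_overlap", "p", "q"],
            index=pd.Index([], name="gene_set"),
        )
    df = pd.DataFrame(
        rows, columns=["gene_set", "genes_in_set", "genes_in_overlap", "p"]
    ).set_index("gene_set")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["q", "gene_set"], kind="mergesort")


@dataclass(frozen=True)
class ListOverlap:
    k: int
    overlap: list[str]
    odds_ratio: float
    p: float


def overlap_two_lists(
    list_a: list[str], list_b: list[str], universe_size: int
) -> ListOverlap:
    """One-sided (enrichment) Fisher exact test for the overlap of two
    gene lists within a universe of `universe_size` genes."""
    a = _folded_unique(list_a, "list_a")
    b = _folded_unique(list_b, "list_b")
    if universe_size < len(a) or universe_size < len(b):
        raise ValueError(
            f"universe_size ({universe_size}) smaller than a list "
            f"({len(a)} / {len(b)})"
        )
    if universe_size < len(a | b):
        raise ValueError(
            f"universe_size ({universe_size}) smaller than the union of the "
            f"two lists ({len(a | b)})"
        )
    shared = sorted(a & b)
    odds, p = fisher_exact_overlap(
        Overlap2x2(k=len(shared), K=len(a), n=len(b), N=universe_size)
    )
    display = {g.casefold(): g for g in list_a}
    return ListOverlap(
        k=len(shared),
        overlap=[display[g] for g in shared],
        odds_ratio=odds,
        p=p,
    )
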