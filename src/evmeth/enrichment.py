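"""Hypergeometric over-representation analysis against GMT collections.

For each gene set S in a collection, with universe size N, annotated set
size K = |S ∩ universe|, query size n and overlap k = |S ∩ query|, the
one-sided p-value is the upper hypergeometric tail P(X >= k).  P-values are
Benjamini–Hochberg adjusted across all tested sets; significance is called
at adjusted p < alpha.  Only over-representation is tested.

The choice of universe materially changes the result; callers must pass it
explicitly in the CLI (the library defaults to requiring it too).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ORA_COLUMNS = ["set", "k", "K", "n", "N", "p", "adj_p", "significant", "genes"]


class GMTParseError(ValueError):
    """Malformed GMT content; message carries the 1-based line number."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. an MSigDB C2 download in GMT form)."""

    name: str
    sets: Mapping[str, frozenset]

    def __len__(self) -> int:
        return len(self.sets)

    def subset_by_size(
        self, min_size: int | None = None, max_size: int | None = None
    ) -> "GeneSetCollection":
        kept = {
            name: genes
            for name, genes in self.sets.items()
            if (min_size is None or len(genes) >= min_size)
            and (max_size is None or len(genes) <= max_size)
        }
        return GeneSetCollection(name=self.name, sets=kept)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then gene symbols."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"line {lineno}: expected name, description and >= 1 gene "
                    f"(got {len(fields)} field(s))"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise GMTParseError(f"line {lineno}: gene set {name!r} is empty")
            if name in sets:
                raise GMTParseError(f"line {lineno}: duplicate gene set name {name!r}")
            sets[name] = frozenset(genes)
    import os

    return GeneSetCollection(name=os.path.basename(str(path)), sets=sets)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # ORA_COLUMNS, sorted by adj_p
    n_query_outside_universe: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    min_size: int | None = None,
    max_size: int | None = None,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation of a query gene list.

    Query genes outside the universe are trimmed (their count is reported).
    Sets with no annotated gene in the universe are skipped; set-size limits
    apply to the annotated size K.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    outside = query - universe
    query &= universe
    if not query:
        raise ValueError("no query gene lies in the universe")
    N, n = len(universe), len(query)

    rows = []
    for name, genes in collection.sets.items():
        annotated = genes & universe
        K = len(annotated)
        if K == 0:
            continue
        if (min_size is not None and K < min_size) or (
            max_size is not None and K > max_size
        ):
            continue
        overlap = sorted(annotated & query)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append((name, k, K, n, N, min(p, 1.0), ",".join(overlap)))
    if not rows:
        return EnrichmentResult(
            table=pd.DataFrame(columns=ORA_COLUMNS),
            n_query_outside_universe=len(outside),
        )
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "genes"])
    _, adj, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["adj_p"] = adj
    df["significant"] = df["adj_p"] < alpha
    df = df.sort_values(["adj_p", "p", "set"], ignore_index=True)
    return EnrichmentResult(
        table=df[ORA_COLUMNS], n_query_outside_universe=len(outside)
    )
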