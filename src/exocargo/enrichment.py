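"""Hypergeometric over-representation analysis over GMT gene-set collections.

For a query of n genes drawn from a universe of N, and an annotated set
of K genes with k of them in the query, the over-representation p-value
is the upper hypergeometric tail P(X >= k). One-sided by design — the
use case is enrichment, not depletion. P-values are Benjamini-Hochberg
adjusted across sets. Two significance conventions are supported:
-log10(p) > threshold (default 2, i.e. p < 0.01) and padj < threshold
(default 0.05).

GO/Reactome/KEGG/Disease-Ontology semantics are not modelled; any GMT
collection can be supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from exocargo.diffexp import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_ora",
    "filter_significant",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable[str]],
                  universe: Iterable[str]) -> "GeneSetCollection":
        uni = frozenset(str(g) for g in universe)
        if not uni:
            raise ValueError("empty universe")
        restricted = {}
        for name, members in sets.items():
            if name in restricted:
                raise ValueError(f"duplicate set name {name!r}")
            restricted[str(name)] = frozenset(str(g) for g in members) & uni
        return cls(restricted, uni)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (name, description, members...) into name -> gene set."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate set name {parts[0]!r} in {path}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    """Write name -> gene-set mappings as a GMT file (sorted, deterministic)."""
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(str(g) for g in sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def hypergeom_ora(
    query: Iterable[str],
    collection: GeneSetCollection | Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of a query against every set.

    Query genes outside the universe are dropped (count logged). Returns
    one row per set — overlap k, set size K, query size n, universe size
    N, p_value = P(X >= k), BH-adjusted p and -log10(p) — sorted by
    ascending p, ties lexicographic by set name.
    """
    if not isinstance(collection, GeneSetCollection):
        if universe is None:
            raise ValueError("universe required when collection is a plain mapping")
        collection = GeneSetCollection.from_dict(collection, universe)
    q_raw = {str(g) for g in query}
    q = q_raw & collection.universe
    dropped = len(q_raw) - len(q)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    n, N = len(q), len(collection.universe)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(q & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        rows.append({"set_name": name, "overlap_k": k, "set_size_K": K,
                     "query_size_n": n, "universe_size_N": N, "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adjusted"] = []
        out["neg_log10_p"] = []
        return out
    out["p_adjusted"] = bh_adjust(out["p_value"])
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    return out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)


def filter_significant(
    results: pd.DataFrame, mode: str = "neg_log10", threshold: float | None = None
) -> pd.DataFrame:
    """Keep significant rows: -log10(p) > threshold (default 2) or padj < threshold (default 0.05)."""
    if mode == "neg_log10":
        cut = 2.0 if threshold is None else threshold
        return results[results["neg_log10_p"] > cut].reset_index(drop=True)
    if mode == "padj":
        cut = 0.05 if threshold is None else threshold
        return results[results["p_adjusted"] < cut].reset_index(drop=True)
    raise ValueError(f"unknown significance mode {mode!r}")
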