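"""Multi-criteria protein-abundance ranking from replicated MS identifications.

Bottom-up proteomics search engines report, per identified protein and
biological replicate, a confidence Score, a sequence Coverage (percent) and
an integrated peak Area. This module implements a weighted composite
abundance score over those three metrics: proteins detected in at least
``min_replicates`` distinct replicates are retained, each metric is
aggregated across the replicates in which the protein was detected,
min-max normalized to [0, 1] across the filtered set, and combined as

    CombinedScore = w_score * NormScore + w_coverage * NormCoverage
                    + w_area * NormArea

with default weights 0.2 / 0.2 / 0.6 — Area, the closest proxy for
abundance, dominates, while Score and Coverage guard identification
quality. The ranked list feeds top-k selection and overlap reporting
against a reference catalogue of vesicle-associated proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankingWeights",
    "OverlapReport",
    "filter_by_replicates",
    "minmax_normalize",
    "combined_score",
    "rank_top_k",
    "overlap_with_reference",
]

logger = logging.getLogger(__name__)

EVIDENCE_COLUMNS = ("accession", "replicate", "score", "coverage", "area")


@dataclass(frozen=True)
class RankingWeights:
    """Non-negative weights for Score, Coverage and Area; must sum to 1."""

    w_score: float = 0.2
    w_coverage: float = 0.2
    w_area: float = 0.6

    def __post_init__(self) -> None:
        if min(self.w_score, self.w_coverage, self.w_area) < 0:
            raise ValueError("weights must be non-negative")
        total = self.w_score + self.w_coverage + self.w_area
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {total!r})")


@dataclass(frozen=True)
class OverlapReport:
    """Set-overlap summary between a query and a reference gene set."""

    n_query: int
    n_reference: int
    n_intersection: int
    n_query_only: int
    n_reference_only: int
    percent_query_in_reference: float
    intersection: frozenset[str]


def _check_evidence(evidence: pd.DataFrame) -> None:
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    if len(evidence):
        dup = evidence.duplicated(subset=["accession", "replicate"])
        if dup.any():
            raise ValueError("duplicate (accession, replicate) rows in evidence")
        cov = evidence["coverage"].to_numpy(dtype=float)
        if np.any((cov < 0) | (cov > 100)):
            raise ValueError("coverage must lie in [0, 100]")


def filter_by_replicates(
    evidence: pd.DataFrame,
    min_replicates: int = 2,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Retain proteins detected in >= ``min_replicates`` distinct replicates.

    Parameters
    ----------
    evidence
        One row per (protein, replicate) detection with columns
        ``accession, replicate, score, coverage, area`` and optionally
        ``gene``.
    min_replicates
        Minimum number of distinct replicates a protein must appear in.
    aggregate
        Cross-replicate aggregation of the three metrics: ``"mean"``
        (default) or ``"sum"``.

    Returns
    -------
    One row per retained protein with ``n_replicates_detected`` and the
    aggregated ``score, coverage, area``, sorted by accession. The counts
    before/after filtering are attached as ``result.attrs``.
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    _check_evidence(evidence)
    if evidence.empty:
        logger.warning("empty evidence table: no proteins to filter")
        out = pd.DataFrame(
            columns=["accession", "gene", "n_replicates_detected", "score", "coverage", "area"]
        )
        out.attrs["n_before"] = 0
        out.attrs["n_after"] = 0
        return out

    has_gene = "gene" in evidence.columns
    grouped = evidence.groupby("accession", sort=True)
    agg: dict[str, object] = {"replicate": "nunique", "score": aggregate,
                              "coverage": aggregate, "area": aggregate}
    if has_gene:
        agg["gene"] = "first"
    summary = grouped.agg(agg).rename(columns={"replicate": "n_replicates_detected"})
    n_before = len(summary)
    summary = summary[summary["n_replicates_detected"] >= min_replicates]
    out = summary.reset_index()
    if not has_gene:
        out["gene"] = None
    out = out[["accession", "gene", "n_replicates_detected", "score", "coverage", "area"]]
    out.attrs["n_before"] = n_before
    out.attrs["n_after"] = len(out)
    logger.info("replicate filter: %d -> %d proteins (min_replicates=%d)",
                n_before, len(out), min_replicates)
    return out


def minmax_normalize(values) -> np.ndarray:
    """Map values to [0, 1] via (v - min) / (max - min); order-preserving.

    A constant column (max == min) maps every value to 0 — any constant
    preserves the induced ranking; 0 is used and a notice is logged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty value list")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        logger.info("constant column under min-max normalization; mapping all to 0")
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def combined_score(
    summary: pd.DataFrame, weights: RankingWeights | None = None
) -> pd.DataFrame:
    """Weighted composite abundance score over the replicate-filtered set.

    Each of Score, Coverage, Area is min-max normalized across the table
    independently, then combined linearly with ``weights``. Rows are ranked
    by descending combined score; ties break lexicographically by
    accession. Rank 1 is the most abundant protein.
    """
    weights = weights or RankingWeights()
    required = {"accession", "score", "coverage", "area"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    out = summary.copy()
    if out.empty:
        for col in ("normalized_score", "normalized_coverage", "normalized_area",
                    "combined_score", "rank"):
            out[col] = []
        return out
    out["normalized_score"] = minmax_normalize(out["score"])
    out["normalized_coverage"] = minmax_normalize(out["coverage"])
    out["normalized_area"] = minmax_normalize(out["area"])
    out["combined_score"] = (
        weights.w_score * out["normalized_score"]
        + weights.w_coverage * out["normalized_coverage"]
        + weights.w_area * out["normalized_area"]
    )
    out = out.sort_values(
        ["combined_score", "accession"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def rank_top_k(ranked: pd.DataFrame, k: int) -> pd.DataFrame:
    """First min(k, n) rows of a ranked table by descending combined score."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if "rank" not in ranked.columns:
        raise ValueError("table is not ranked; run combined_score first")
    return ranked.nsmallest(min(k, len(ranked)), "rank").reset_index(drop=True)


def overlap_with_reference(query: set[str], reference: set[str]) -> OverlapReport:
    """Overlap of a query gene set with a reference catalogue.

    Matching is case-insensitive; the report's percent is
    100 * |query ∩ reference| / |query|.
    """
    if not query:
        raise ValueError("empty query set")
    if not reference:
        raise ValueError("empty reference set")
    q = {str(g).upper() for g in query}
    r = {str(g).upper() for g in reference}
    inter = q & r
    return OverlapReport(
        n_query=len(q),
        n_reference=len(r),
        n_intersection=len(inter),
        n_query_only=len(q - r),
        n_reference_only=len(r - q),
        percent_query_in_reference=100.0 * len(inter) / len(q),
        intersection=frozenset(inter),
    )
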