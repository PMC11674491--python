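"""Proteogenomic integration of miRNA-target and protein-protein interaction layers.

A dually affected gene (DAG) is a gene that is simultaneously (i) a
validated target of at least one of the profiled exosomal miRNAs and
(ii) a physical interactor (at or above a confidence cutoff, default
0.7) of at least one of the profiled exosomal proteins — i.e. a gene in
a prospective recipient cell that the vesicle cargo can hit through two
independent molecular routes. This module filters the two edge layers,
expands PPI shells around the protein seeds with deterministic caps,
intersects the layers into a DAG report, assembles a layered network
(networkx), groups target genes by how many distinct miRNAs hit them,
and ranks genes by disease-association publication counts.

Edge tables are plain pandas DataFrames: targets with columns
``mirna, gene, evidence, source_db`` (evidence: ';'-separated method
labels) and PPI with ``protein_a, protein_b, confidence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "InteractomeConfig",
    "DAGReport",
    "VALIDATED_EVIDENCE_KEYWORDS",
    "merge_target_edges",
    "filter_target_edges_by_evidence",
    "filter_ppi_by_confidence",
    "expand_shells",
    "identify_dags",
    "build_layered_network",
    "group_genes_by_mirna_multiplicity",
    "rank_by_disease_publications",
    "export_network",
    "read_graphml",
]

VALIDATED_EVIDENCE_KEYWORDS: tuple[str, ...] = (
    "reporter assay",
    "luciferase",
    "western blot",
    "immunoblot",
    "qrt-pcr",
)

LAYERS = ("exosomal_protein", "dag", "mirna_only_target", "mirna")


@dataclass(frozen=True)
class InteractomeConfig:
    """Filtering and shell-expansion settings.

    min_confidence
        PPI edges at or above this score are kept (inclusive, default 0.7).
    max_first_shell / max_second_shell
        Global caps on interactors added around the seed proteins
        (defaults 10 and 5).
    validated_evidence_keywords
        Case-insensitive substrings that mark a miRNA-target edge as
        experimentally validated.
    """

    min_confidence: float = 0.7
    max_first_shell: int = 10
    max_second_shell: int = 5
    validated_evidence_keywords: tuple[str, ...] = VALIDATED_EVIDENCE_KEYWORDS

    def __post_init__(self) -> None:
        if not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence must be in [0, 1]")
        if self.max_first_shell < 0 or self.max_second_shell < 0:
            raise ValueError("shell caps must be >= 0")
        if not self.validated_evidence_keywords:
            raise ValueError("validated_evidence_keywords must be non-empty")


@dataclass
class DAGReport:
    """Outcome of the dual-layer intersection.

    dags
        Genes targeted by >= 1 profiled miRNA and interacting with >= 1
        profiled exosomal protein after both filters.
    n_targeting_mirnas / n_interacting_proteins
        Per-DAG counts on the two axes (each >= 1 by construction).
    proteins_that_are_targets
        Exosomal proteins that themselves appear as validated target
        genes ("x out of y" statistic).
    """

    dags: set[str]
    n_targeting_mirnas: dict[str, int]
    n_interacting_proteins: dict[str, int]
    mirna_only_targets: set[str]
    proteins_that_are_targets: list[str]
    n_proteins_total: int
    disease_ranked: list[tuple[str, int]] = field(default_factory=list)

    @property
    def protein_target_overlap(self) -> str:
        return f"{len(self.proteins_that_are_targets)} out of {self.n_proteins_total}"


# ---------------------------------------------------------------------------
# Edge filters
# ---------------------------------------------------------------------------

def _evidence_set(value) -> set[str]:
    if isinstance(value, str):
        return {v.strip() for v in value.split(";") if v.strip()}
    return {str(v).strip() for v in value}


def merge_target_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Merge duplicate (mirna, gene) rows across sources; evidence-set union."""
    if edges.empty:
        return edges.copy()
    rows = []
    for (mirna, gene), sub in edges.groupby(["mirna", "gene"], sort=True):
        evid: set[str] = set()
        for e in sub["evidence"]:
            evid |= _evidence_set(e)
        sources = sorted({str(s) for s in sub.get("source_db", pd.Series(dtype=str))})
        rows.append({"mirna": mirna, "gene": gene,
                     "evidence": ";".join(sorted(evid)),
                     "source_db": ";".join(sources)})
    return pd.DataFrame(rows)


def filter_target_edges_by_evidence(
    edges: pd.DataFrame, keywords: Sequence[str] = VALIDATED_EVIDENCE_KEYWORDS
) -> pd.DataFrame:
    """Keep edges whose evidence contains >= 1 keyword (case-insensitive substring)."""
    if not keywords:
        raise ValueError("keywords must be non-empty")
    if edges.empty:
        return edges.copy()
    kws = [k.lower() for k in keywords]

    def validated(e) -> bool:
        labels = [lab.lower() for lab in _evidence_set(e)]
        return any(k in lab for k in kws for lab in labels)

    return edges[edges["evidence"].map(validated)].reset_index(drop=True)


def filter_ppi_by_confidence(edges: pd.DataFrame, min_confidence: float = 0.7) -> pd.DataFrame:
    """Keep PPI edges with confidence >= min_confidence (inclusive boundary)."""
    if edges.empty:
        return edges.copy()
    conf = edges["confidence"].astype(float)
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError("PPI confidences must lie in [0, 1]")
    return edges[conf >= min_confidence].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Shell expansion
# ---------------------------------------------------------------------------

def expand_shells(
    seeds: Iterable[str],
    ppi_edges: pd.DataFrame,
    config: InteractomeConfig | None = None,
) -> dict[str, int]:
    """Label nodes with their PPI shell around the seed proteins.

    Shell 0 = seeds. Shell 1 = up to ``max_first_shell`` non-seed
    neighbors of seeds, chosen by highest maximum confidence of an edge
    into the current set (ties lexicographic on node id); shell 2 = up to
    ``max_second_shell`` new neighbors of shell-1 nodes, same rule. Caps
    apply globally, not per seed.
    """
    config = config or InteractomeConfig()
    seeds = set(seeds)
    adj: dict[str, dict[str, float]] = {}
    for _, row in ppi_edges.iterrows():
        a, b, c = str(row["protein_a"]), str(row["protein_b"]), float(row["confidence"])
        if a == b:
            continue
        adj.setdefault(a, {})[b] = max(adj.get(a, {}).get(b, 0.0), c)
        adj.setdefault(b, {})[a] = max(adj.get(b, {}).get(a, 0.0), c)

    shells = {s: 0 for s in seeds}

    def pick(frontier: set[str], cap: int) -> list[str]:
        scores: dict[str, float] = {}
        for node in frontier:
            for nb, c in adj.get(node, {}).items():
                if nb not in shells:
                    scores[nb] = max(scores.get(nb, 0.0), c)
        ordered = sorted(scores, key=lambda n: (-scores[n], n))
        return ordered[:cap]

    first = pick(seeds, config.max_first_shell)
    for n in first:
        shells[n] = 1
    second = pick(set(first), config.max_second_shell)
    for n in second:
        shells[n] = 2
    return shells


# ---------------------------------------------------------------------------
# DAG identification and network assembly
# ---------------------------------------------------------------------------

def identify_dags(
    target_edges: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    exosomal_proteins: Iterable[str],
    top_mirnas: Iterable[str],
    config: InteractomeConfig | None = None,
    prefiltered: bool = False,
) -> DAGReport:
    """Intersect the validated-target and confident-PPI layers.

    DAG set = {g : some top miRNA targets g} ∩ {g : g interacts with
    some exosomal protein}. Unless ``prefiltered``, the evidence and
    confidence filters are applied first. Also reports the exosomal
    proteins that are themselves validated targets.
    """
    config = config or InteractomeConfig()
    proteins = sorted({str(p) for p in exosomal_proteins})
    mirnas = {str(m) for m in top_mirnas}
    if not proteins:
        raise ValueError("empty exosomal protein list")
    if not mirnas:
        raise ValueError("empty top-miRNA list")
    if not prefiltered:
        target_edges = filter_target_edges_by_evidence(
            merge_target_edges(target_edges), config.validated_evidence_keywords
        )
        ppi_edges = filter_ppi_by_confidence(ppi_edges, config.min_confidence)

    tgt = target_edges[target_edges["mirna"].astype(str).isin(mirnas)] if len(target_edges) else target_edges
    targeting: dict[str, set[str]] = {}
    for _, row in tgt.iterrows():
        targeting.setdefault(str(row["gene"]), set()).add(str(row["mirna"]))

    pset = set(proteins)
    interacting: dict[str, set[str]] = {}
    for _, row in ppi_edges.iterrows():
        a, b = str(row["protein_a"]), str(row["protein_b"])
        if a == b:
            continue
        if b in pset:
            interacting.setdefault(a, set()).add(b)
        if a in pset:
            interacting.setdefault(b, set()).add(a)

    dags = set(targeting) & set(interacting)
    return DAGReport(
        dags=dags,
        n_targeting_mirnas={g: len(targeting[g]) for g in dags},
        n_interacting_proteins={g: len(interacting[g]) for g in dags},
        mirna_only_targets=set(targeting) - dags,
        proteins_that_are_targets=sorted(p for p in pset if p in targeting),
        n_proteins_total=len(pset),
    )


def build_layered_network(
    report: DAGReport,
    target_edges: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    exosomal_proteins: Iterable[str],
    top_mirnas: Iterable[str],
    config: InteractomeConfig | None = None,
    prefiltered: bool = False,
) -> nx.Graph:
    """Assemble the layered miRNA / target-gene / protein network.

    Node layers partition the node set: ``exosomal_protein`` (dual roles
    recorded in the ``is_target`` / ``is_dag_qualified`` attributes),
    ``dag``, ``mirna_only_target`` and ``mirna``. Edges carry
    ``type`` = "targets" (miRNA -> gene) or "interacts" (PPI).
    """
    config = config or InteractomeConfig()
    if not prefiltered:
        target_edges = filter_target_edges_by_evidence(
            merge_target_edges(target_edges), config.validated_evidence_keywords
        )
        ppi_edges = filter_ppi_by_confidence(ppi_edges, config.min_confidence)
    proteins = {str(p) for p in exosomal_proteins}
    mirnas = {str(m) for m in top_mirnas}

    g = nx.Graph()
    for p in sorted(proteins):
        g.add_node(p, layer="exosomal_protein",
                   is_target=p in set(report.proteins_that_are_targets),
                   is_dag_qualified=p in report.dags)
    for m in sorted(mirnas):
        g.add_node(m, layer="mirna")
    for gene in sorted(report.dags - proteins):
        g.add_node(gene, layer="dag")
    for gene in sorted(report.mirna_only_targets - proteins):
        g.add_node(gene, layer="mirna_only_target")

    for _, row in target_edges.iterrows():
        m, gene = str(row["mirna"]), str(row["gene"])
        if m in mirnas and gene in g:
            g.add_edge(m, gene, type="targets")
    for _, row in ppi_edges.iterrows():
        a, b = str(row["protein_a"]), str(row["protein_b"])
        if a == b:
            continue
        if a in g and b in g and (a in proteins or b in proteins):
            g.add_edge(a, b, type="interacts", confidence=float(row["confidence"]))
    return g


def group_genes_by_mirna_multiplicity(
    target_edges: pd.DataFrame, mirnas: Iterable[str]
) -> dict[str, set[str]]:
    """Group target genes by their count of distinct targeting miRNAs.

    Returns {"1": ..., "2": ..., ">=3": ...}; duplicate edges count once
    (distinct-miRNA rule).
    """
    mset = {str(m) for m in mirnas}
    if not mset:
        raise ValueError("empty miRNA subset")
    counts: dict[str, set[str]] = {}
    for _, row in target_edges.iterrows():
        m = str(row["mirna"])
        if m in mset:
            counts.setdefault(str(row["gene"]), set()).add(m)
    groups: dict[str, set[str]] = {"1": set(), "2": set(), ">=3": set()}
    for gene, ms in counts.items():
        key = "1" if len(ms) == 1 else "2" if len(ms) == 2 else ">=3"
        groups[key].add(gene)
    return groups


def rank_by_disease_publications(
    genes: Iterable[str], associations: Mapping[str, int] | pd.DataFrame
) -> list[tuple[str, int]]:
    """Rank genes by disease-association publication count, descending.

    Ties break lexicographically; genes absent from the table score 0.
    """
    if isinstance(associations, pd.DataFrame):
        associations = dict(zip(associations["gene"].astype(str),
                                associations["n_publications"].astype(int)))
    table = {str(g): int(n) for g, n in associations.items()}
    if any(n < 0 for n in table.values()):
        raise ValueError("publication counts must be non-negative")
    ranked = [(str(g), table.get(str(g), 0)) for g in genes]
    return sorted(ranked, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_network(network: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write the layered network as GraphML (lossless), SIF, or a TSV edge list."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(network.nodes(data=True)))
    ordered.add_edges_from(sorted((min(u, v), max(u, v), d)
                                  for u, v, d in network.edges(data=True)))
    if fmt == "graphml":
        nx.write_graphml(ordered, str(path))
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in ordered.edges(data=True):
                fh.write(f"{u}\t{d.get('type', 'edge')}\t{v}\n")
    elif fmt in ("tsv", "edgelist"):
        rows = [{"source": u, "target": v, "type": d.get("type", ""),
                 "confidence": d.get("confidence", "")}
                for u, v, d in ordered.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "type", "confidence"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a network previously exported as GraphML."""
    return nx.read_graphml(str(path))
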