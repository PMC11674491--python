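"""Synthetic exosome-cargo study generator with planted ground truth.

Every input the pipeline consumes can be generated here from a single
seed: a replicated protein-identification table (Score/Coverage/Area), a
two-group negative-binomial miRNA count matrix with planted log2 fold
changes, adapter-bearing ~50 nt small-RNA reads realizing those counts, a
mature-miRNA reference, miRNA-target and PPI edge tables with planted
dually affected genes, a disease-association table, and GMT gene-set
collections. The accompanying :class:`PlantedTruth` records what was
planted, so downstream modules can be checked for exact recovery.

The defaults emulate the shape of a small two-cell-line exosome study:
three biological replicates per condition, on the order of 70 miRNAs
consistently detected, a protein table whose >= 2-of-3-replicate filtrate
is near 70 proteins, NB dispersion 0.1, log-uniform baseline abundances
over roughly 10-3000 expected counts, and mild log-normal library-size
variation. Identifiers are synthetic tokens (P0001, m0001, G0001).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from exocargo import proteomics, smallrna
from exocargo.smallrna import FastqRead

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "gen_protein_table",
    "gen_mirna_counts",
    "gen_reference",
    "gen_reads",
    "gen_interactome",
    "gen_genesets",
    "simulate_all",
]

# distinct RNG streams per generator, all derived from cfg.seed
_STREAM = {"proteins": 1, "counts": 2, "reference": 3, "reads": 4,
           "interactome": 5, "genesets": 6}

VALIDATED_LABELS = (
    "Luciferase reporter assay",
    "Western blot",
    "qRT-PCR",
    "Reporter assay",
)
NONVALIDATED_LABELS = (
    "Microarray",
    "Next Generation Sequencing",
    "CLIP-Seq",
    "Degradome sequencing",
    "Computational prediction",
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings (a single seed drives everything).

    Protein table: ``n_proteins`` candidates, each independently detected
    in a replicate with probability ``detect_prob``; metric values are
    latent per-protein draws (Score positive continuous, Coverage in
    (0, 100], Area log-normal heavy-tailed), identical across detected
    replicates unless ``metric_noise_sd`` > 0.

    Counts: ``n_mirnas`` miRNAs in two groups (A vs B) of ``n_per_group``
    samples; baselines log-uniform 10**U(mean_log_range); a fraction
    ``frac_de`` carries a planted signed log2 fold change of magnitude
    ``planted_log2fc`` in group A (or exactly ``n_up``/``n_down`` effects
    when given, drawn at baselines 10**U(de_mean_log_range) so planted
    effects sit at well-measured abundances); counts are NB with
    variance = mu + dispersion * mu^2; per-sample library-size
    multipliers are log-normal(0, libsize_sigma).

    Reads: each requested count becomes a read of ``read_length`` nt =
    mature sequence + 3' ``adapter`` + random padding, with per-base
    substitution probability ``error_rate``; a fraction
    ``low_quality_frac`` of reads receives a failing quality tier (mean
    Phred well below 25), the rest a passing tier (well above 25).
    """

    seed: int = 0
    # proteins
    n_proteins: int = 240
    n_replicates: int = 3
    detect_prob: float = 0.35
    metric_noise_sd: float = 0.0
    # miRNA counts
    n_mirnas: int = 72
    n_per_group: int = 3
    frac_de: float = 0.25
    planted_log2fc: float = 3.0
    dispersion: float = 0.1
    mean_log_range: tuple[float, float] = (1.0, 3.5)
    de_mean_log_range: tuple[float, float] | None = None
    libsize_sigma: float = 0.15
    n_up: int | None = None
    n_down: int | None = None
    # reads
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    error_rate: float = 0.001
    low_quality_frac: float = 0.0
    read_length: int = 50
    # interactome / gene sets
    gene_universe_size: int = 150
    n_true_dags: int = 15
    n_genesets: int = 10

    def __post_init__(self) -> None:
        for name in ("detect_prob", "frac_de", "error_rate", "low_quality_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.adapter) < 6:
            raise ValueError("adapter must be at least 6 nt")
        if self.mean_log_range[0] > self.mean_log_range[1]:
            raise ValueError("mean_log_range must be (lo, hi) with lo <= hi")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, JSON-serializable.

    de_mirnas maps miRNA id -> signed planted log2FC (group A over B);
    per_mirna_true_counts maps miRNA id -> per-sample expected counts.
    """

    de_mirnas: dict[str, float] = field(default_factory=dict)
    true_dags: set[str] = field(default_factory=set)
    true_top_proteins: list[str] = field(default_factory=list)
    true_top_mirnas: list[str] = field(default_factory=list)
    per_mirna_true_counts: dict[str, dict[str, float]] = field(default_factory=dict)
    library_sizes: dict[str, float] = field(default_factory=dict)
    targeted_proteins: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["true_dags"] = sorted(self.true_dags)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["true_dags"] = set(payload.get("true_dags", []))
        return cls(**payload)

    def merge(self, other: "PlantedTruth") -> "PlantedTruth":
        return PlantedTruth(
            de_mirnas={**self.de_mirnas, **other.de_mirnas},
            true_dags=self.true_dags | other.true_dags,
            true_top_proteins=other.true_top_proteins or self.true_top_proteins,
            true_top_mirnas=other.true_top_mirnas or self.true_top_mirnas,
            per_mirna_true_counts={**self.per_mirna_true_counts,
                                   **other.per_mirna_true_counts},
            library_sizes={**self.library_sizes, **other.library_sizes},
            targeted_proteins=other.targeted_proteins or self.targeted_proteins,
        )


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed), _STREAM[stream]])


# ---------------------------------------------------------------------------
# Protein table
# ---------------------------------------------------------------------------

def gen_protein_table(cfg: SimConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Per-replicate protein identification table with planted abundance order.

    Latent per-protein metrics: Score log-normal, Coverage scaled Beta in
    (0, 100], Area log-normal with heavy tail. Each protein appears in a
    replicate with probability ``detect_prob``. The truth records the
    composite-score ordering implied by the latent metrics aggregated
    over the replicates in which each protein was detected (with the
    default ``metric_noise_sd`` = 0 the observed table carries exactly
    those values).
    """
    rng = _rng(cfg.seed, "proteins")
    n = cfg.n_proteins
    acc = [f"P{i + 1:04d}" for i in range(n)]
    genes = [f"GP{i + 1:04d}" for i in range(n)]
    score = np.exp(rng.normal(np.log(200.0), 0.8, n))
    coverage = 100.0 * rng.beta(2.0, 3.0, n)
    area = np.exp(rng.normal(np.log(1e7), 2.0, n))  # heavy-tailed
    detected = rng.random((n, cfg.n_replicates)) < cfg.detect_prob

    rows = []
    for i in range(n):
        for r in range(cfg.n_replicates):
            if not detected[i, r]:
                continue
            noise = (np.exp(rng.normal(0.0, cfg.metric_noise_sd, 3))
                     if cfg.metric_noise_sd > 0 else np.ones(3))
            rows.append({
                "accession": acc[i], "gene": genes[i], "replicate": r + 1,
                "score": score[i] * noise[0],
                "coverage": min(100.0, coverage[i] * noise[1]),
                "area": area[i] * noise[2],
            })
    table = pd.DataFrame(
        rows, columns=["accession", "gene", "replicate", "score", "coverage", "area"]
    )

    # truth: ranking implied by the latent metrics over >=2-replicate proteins
    kept = detected.sum(axis=1) >= 2
    latent = pd.DataFrame({
        "accession": np.array(acc)[kept], "gene": np.array(genes)[kept],
        "score": score[kept], "coverage": coverage[kept], "area": area[kept],
    })
    ranked = proteomics.combined_score(latent)
    truth = PlantedTruth(true_top_proteins=list(ranked["accession"]))
    return table, truth


# ---------------------------------------------------------------------------
# miRNA counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance = mean + alpha * mean^2 (Poisson when alpha = 0)."""
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def gen_mirna_counts(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, str], PlantedTruth]:
    """Two-group NB count matrix with planted signed log2 fold changes.

    Returns (counts, groups, truth): counts is miRNA x sample with
    samples A1..An then B1..Bn, groups maps sample -> "A"/"B", and the
    truth holds the planted effects (positive = higher in group A), the
    per-sample expected counts and the library-size multipliers.
    """
    rng = _rng(cfg.seed, "counts")
    n, npg = cfg.n_mirnas, cfg.n_per_group
    mirnas = [f"m{i + 1:04d}" for i in range(n)]
    samples = [f"A{j + 1}" for j in range(npg)] + [f"B{j + 1}" for j in range(npg)]
    groups = {s: s[0] for s in samples}

    base = 10.0 ** rng.uniform(*cfg.mean_log_range, n)
    if cfg.n_up is not None or cfg.n_down is not None:
        n_up, n_down = cfg.n_up or 0, cfg.n_down or 0
    else:
        n_de = int(round(cfg.frac_de * n))
        n_up, n_down = (n_de + 1) // 2, n_de // 2
    if n_up + n_down > n:
        raise ValueError("more planted effects than miRNAs")
    de_idx = rng.choice(n, size=n_up + n_down, replace=False)
    lfc = np.zeros(n)
    lfc[de_idx[:n_up]] = cfg.planted_log2fc
    lfc[de_idx[n_up:]] = -cfg.planted_log2fc
    if de_idx.size:
        de_lo, de_hi = cfg.de_mean_log_range or (
            max(np.log10(200.0), cfg.mean_log_range[0]), cfg.mean_log_range[1])
        base[de_idx] = 10.0 ** rng.uniform(de_lo, max(de_hi, de_lo), de_idx.size)

    libsize = np.exp(rng.normal(0.0, cfg.libsize_sigma, 2 * npg))
    mu = base[:, None] * np.where(
        np.array([g == "A" for g in (groups[s] for s in samples)]),
        2.0 ** lfc[:, None], 1.0) * libsize[None, :]
    counts = _nb_draw(rng, mu, cfg.dispersion)

    matrix = pd.DataFrame(counts, index=pd.Index(mirnas, name="mirna"),
                          columns=samples, dtype=int)
    truth = PlantedTruth(
        de_mirnas={mirnas[i]: float(lfc[i]) for i in de_idx},
        per_mirna_true_counts={m: {s: float(mu[i, j]) for j, s in enumerate(samples)}
                               for i, m in enumerate(mirnas)},
        library_sizes={s: float(libsize[j]) for j, s in enumerate(samples)},
    )
    # ranking implied by the realized counts under the documented reduction
    consistent = smallrna.consistency_filter(matrix)
    if len(consistent) and (consistent.sum(axis=0) > 0).all():
        truth.true_top_mirnas = smallrna.rank_mirnas_top_k(
            smallrna.cpm_normalize(consistent), k=20)
    return matrix, groups, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def gen_reference(cfg: SimConfig) -> dict[str, str]:
    """Mature-miRNA reference: n_mirnas sequences of 18-26 nt.

    Sequences avoid the first 6 nt of the adapter and are pairwise
    non-substring, so error-free reads trim and map unambiguously.
    """
    rng = _rng(cfg.seed, "reference")
    motif = cfg.adapter[:6].upper()
    ref: dict[str, str] = {}
    seqs: list[str] = []
    for i in range(cfg.n_mirnas):
        for _ in range(1000):
            length = int(rng.integers(18, 27))
            seq = "".join(rng.choice(BASES, length))
            if motif in seq:
                continue
            if any(seq in s or s in seq for s in seqs):
                continue
            seqs.append(seq)
            ref[f"m{i + 1:04d}"] = seq
            break
        else:  # pragma: no cover - would need absurd parameters
            raise RuntimeError("could not draw a non-conflicting mature sequence")
    return ref


def _quality_string(rng: np.random.Generator, length: int, passing: bool) -> str:
    lo, hi = (36, 41) if passing else (8, 21)
    vals = rng.integers(lo, hi, length) + smallrna.PHRED_OFFSET
    return "".join(chr(int(v)) for v in vals)


def gen_reads(
    reference: Mapping[str, str],
    per_mirna_counts: Mapping[str, Mapping[str, int]],
    cfg: SimConfig,
) -> dict[str, list[FastqRead]]:
    """Reads realizing requested per-(sample, miRNA) counts.

    Each read is mature sequence + 3' adapter, padded with random bases
    and truncated to ``read_length`` nt, with substitution errors at
    ``error_rate`` and a pass/fail quality tier straddling Q25. The total
    read count per sample equals the sum of requested counts.
    """
    if not reference:
        raise ValueError("empty mature reference")
    for counts in per_mirna_counts.values():
        unknown = set(counts) - set(reference)
        if unknown:
            raise ValueError(f"counts reference unknown miRNAs: {sorted(unknown)[:5]}")
    rng = _rng(cfg.seed, "reads")
    out: dict[str, list[FastqRead]] = {}
    for sample in per_mirna_counts:
        reads: list[FastqRead] = []
        for mirna in sorted(per_mirna_counts[sample]):
            mature = reference[mirna]
            count = int(per_mirna_counts[sample][mirna])
            template = (mature + cfg.adapter)[: cfg.read_length]
            pad_len = cfg.read_length - len(template)
            for i in range(count):
                seq = template + ("".join(rng.choice(BASES, pad_len)) if pad_len else "")
                if cfg.error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                    hits = np.nonzero(rng.random(len(seq)) < cfg.error_rate)[0]
                    for pos in hits:
                        choices = [b for b in b"ACGT" if bytes([b]) != arr[pos]]
                        arr[pos] = bytes([choices[int(rng.integers(3))]])
                    seq = arr.tobytes().decode()
                passing = rng.random() >= cfg.low_quality_frac
                reads.append(FastqRead(f"{sample}:{mirna}:{i}", seq,
                                       _quality_string(rng, len(seq), passing)))
        out[sample] = reads
    return out


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def gen_interactome(
    gene_universe_size: int,
    exosomal_proteins: Sequence[str],
    top_mirnas: Sequence[str],
    n_true_dags: int,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """miRNA-target and PPI edge tables with exactly planted DAGs.

    Exactly ``n_true_dags`` genes receive both a validated miRNA-target
    edge and a >= 0.7-confidence PPI edge to an exosomal protein. Decoy
    genes receive only one edge kind, a sub-threshold PPI score, or
    non-validated evidence, so every documented filter is exercised.
    Roughly half the exosomal proteins also appear as validated target
    genes (the "x out of y" overlap statistic); those proteins receive no
    qualifying PPI edge of their own, keeping the planted DAG set exact.
    A disease table assigns publication counts, boosted for planted DAGs.
    """
    if n_true_dags > gene_universe_size:
        raise ValueError("n_true_dags exceeds the gene universe")
    if n_true_dags > 0 and (not exosomal_proteins or not top_mirnas):
        raise ValueError("planting DAGs requires proteins and miRNAs")
    rng = _rng(cfg.seed, "interactome")
    genes = [f"G{i + 1:04d}" for i in range(gene_universe_size)]
    order = list(rng.permutation(gene_universe_size))
    true_dags = [genes[i] for i in order[:n_true_dags]]
    rest = [genes[i] for i in order[n_true_dags:]]
    quarter = len(rest) // 4
    decoy_target_only = rest[:quarter]
    decoy_ppi_only = rest[quarter:2 * quarter]
    decoy_nonvalidated = rest[2 * quarter:3 * quarter]
    decoy_subthreshold = rest[3 * quarter:]

    proteins = [str(p) for p in exosomal_proteins]
    mirnas = [str(m) for m in top_mirnas]

    target_rows: list[dict] = []
    ppi_rows: list[dict] = []

    def add_targets(gene: str, validated: bool, n_edges: int) -> None:
        pool = VALIDATED_LABELS if validated else NONVALIDATED_LABELS
        for m in rng.choice(len(mirnas), size=min(n_edges, len(mirnas)), replace=False):
            target_rows.append({
                "mirna": mirnas[int(m)], "gene": gene,
                "evidence": str(pool[int(rng.integers(len(pool)))]),
                "source_db": ("miRTarBase", "TarBase", "miRecords")[int(rng.integers(3))],
            })

    def add_ppi(gene: str, high: bool, n_edges: int, partners: Sequence[str]) -> None:
        lo, hi = (0.7, 1.0) if high else (0.15, 0.695)
        for p in rng.choice(len(partners), size=min(n_edges, len(partners)), replace=False):
            ppi_rows.append({
                "protein_a": gene, "protein_b": partners[int(p)],
                "confidence": round(float(rng.uniform(lo, hi)), 3),
            })

    if proteins and mirnas:
        for gene in true_dags:
            add_targets(gene, True, int(rng.integers(1, 4)))
            add_ppi(gene, True, int(rng.integers(1, 3)), proteins)
        for gene in decoy_target_only:
            add_targets(gene, True, int(rng.integers(1, 3)))
        for gene in decoy_ppi_only:
            add_ppi(gene, True, int(rng.integers(1, 3)), proteins)
        for gene in decoy_nonvalidated:
            add_targets(gene, False, int(rng.integers(1, 3)))
            add_ppi(gene, True, 1, proteins)
        for gene in decoy_subthreshold:
            add_targets(gene, True, int(rng.integers(1, 3)))
            add_ppi(gene, False, 1, proteins)

        # some exosomal proteins are themselves validated targets; they get
        # no qualifying PPI edge, so the planted DAG set stays exact
        n_prot_targets = len(proteins) // 2
        targeted_proteins = sorted(
            proteins[int(i)] for i in rng.choice(len(proteins), n_prot_targets, replace=False))
        for p in targeted_proteins:
            add_targets(p, True, int(rng.integers(1, 3)))
        untargeted = [p for p in proteins if p not in set(targeted_proteins)]
        for _ in range(min(5, max(0, len(untargeted) - 1))):
            a, b = rng.choice(len(untargeted), 2, replace=False)
            ppi_rows.append({"protein_a": untargeted[int(a)],
                             "protein_b": untargeted[int(b)],
                             "confidence": round(float(rng.uniform(0.7, 1.0)), 3)})
    else:
        targeted_proteins = []

    targets = pd.DataFrame(target_rows, columns=["mirna", "gene", "evidence", "source_db"])
    ppi = pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "confidence"])

    disease_genes = genes + list(proteins)
    pubs = rng.poisson(3.0, len(disease_genes))
    boost = {g: int(rng.poisson(15.0)) for g in true_dags}
    disease = pd.DataFrame({
        "gene": disease_genes,
        "n_publications": [int(p) + boost.get(g, 0) for g, p in zip(disease_genes, pubs)],
    })
    truth = PlantedTruth(true_dags=set(true_dags), targeted_proteins=list(targeted_proteins))
    return targets, ppi, disease, truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def gen_genesets(
    gene_universe: Sequence[str],
    n_sets: int,
    enriched_set_overlap: float,
    seed: int,
    query: Iterable[str] | None = None,
    random_set_size: tuple[int, int] = (10, 30),
) -> tuple[dict[str, set[str]], str]:
    """GMT collection with one set overlapping a designated query.

    The set named ``enriched_set`` shares ``enriched_set_overlap`` of the
    query's genes (query defaults to a random draw); the other sets are
    random draws from the universe. Returns (sets, enriched-set name).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not 0 <= enriched_set_overlap <= 1:
        raise ValueError("overlap fraction must be in [0, 1]")
    universe = [str(g) for g in gene_universe]
    if not universe:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng([int(seed), _STREAM["genesets"]])
    if query is None:
        qsize = min(max(5, len(universe) // 10), len(universe))
        query = [universe[int(i)] for i in rng.choice(len(universe), qsize, replace=False)]
    query = sorted({str(g) for g in query} & set(universe))
    if not query:
        raise ValueError("query has no genes inside the universe")

    sets: dict[str, set[str]] = {}
    n_shared = int(round(enriched_set_overlap * len(query)))
    shared = {query[int(i)] for i in rng.choice(len(query), n_shared, replace=False)}
    outside = sorted(set(universe) - set(query))
    n_fill = len(query) - n_shared
    fill = ({outside[int(i)] for i in rng.choice(len(outside), min(n_fill, len(outside)),
                                                 replace=False)} if outside and n_fill else set())
    sets["enriched_set"] = shared | fill
    lo, hi = random_set_size
    for j in range(n_sets - 1):
        size = int(rng.integers(lo, min(hi, len(universe)) + 1))
        sets[f"random_set_{j + 1:03d}"] = {
            universe[int(i)] for i in rng.choice(len(universe), size, replace=False)}
    return sets, "enriched_set"


# ---------------------------------------------------------------------------
# End-to-end artifact writer
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig, outdir: str | Path) -> PlantedTruth:
    """Generate and write every pipeline input under ``outdir``.

    Artifacts: proteins.tsv, counts.tsv, groups.tsv, mature.fa,
    reads_<sample>.fastq, targets.tsv, ppi.tsv, disease.tsv,
    genesets.gmt and truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteins_tbl, truth_p = gen_protein_table(cfg)
    proteins_tbl.to_csv(outdir / "proteins.tsv", sep="\t", index=False)

    matrix, groups, truth_c = gen_mirna_counts(cfg)
    matrix.to_csv(outdir / "counts.tsv", sep="\t")
    pd.DataFrame({"sample": list(groups), "group": list(groups.values())}).to_csv(
        outdir / "groups.tsv", sep="\t", index=False)

    reference = gen_reference(cfg)
    with open(outdir / "mature.fa", "w") as fh:
        for mid in sorted(reference):
            fh.write(f">{mid}\n{reference[mid]}\n")
    per_sample = {s: {m: int(matrix.at[m, s]) for m in matrix.index} for s in matrix.columns}
    for sample, reads in gen_reads(reference, per_sample, cfg).items():
        smallrna.write_fastq(reads, outdir / f"reads_{sample}.fastq")

    exo_proteins = sorted(
        proteomics.filter_by_replicates(proteins_tbl, min_replicates=2)["accession"])
    top_mirnas = truth_c.true_top_mirnas or list(matrix.index[:20])
    targets, ppi, disease, truth_i = gen_interactome(
        cfg.gene_universe_size, exo_proteins, top_mirnas, cfg.n_true_dags, cfg)
    targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    ppi.to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    disease.to_csv(outdir / "disease.tsv", sep="\t", index=False)

    universe = [f"G{i + 1:04d}" for i in range(cfg.gene_universe_size)]
    sets, _ = gen_genesets(universe, cfg.n_genesets, 0.8, cfg.seed,
                           query=sorted(truth_i.true_dags) or None)
    from exocargo.enrichment import write_gmt
    write_gmt(sets, outdir / "genesets.gmt")

    truth = truth_p.merge(truth_c).merge(truth_i)
    truth.to_json(outdir / "truth.json")
    return truth
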