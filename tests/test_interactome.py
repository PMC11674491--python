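"""Edge filters, shell expansion, DAG identification and network assembly."""

import numpy as np
import pandas as pd
import pytest

from exocargo import simulate
from exocargo.interactome import (
    InteractomeConfig,
    build_layered_network,
    expand_shells,
    export_network,
    filter_ppi_by_confidence,
    filter_target_edges_by_evidence,
    group_genes_by_mirna_multiplicity,
    identify_dags,
    merge_target_edges,
    rank_by_disease_publications,
    read_graphml,
)


def targets_df(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "evidence", "source_db"])


def ppi_df(rows):
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])


def brute_force_dags(targets, ppi, proteins, mirnas, min_conf=0.7, validated_only=True):
    """Naive set-intersection oracle for the dual-affection definition."""
    keywords = ("reporter assay", "luciferase", "western blot", "immunoblot", "qrt-pcr")
    targeted = set()
    for _, r in targets.iterrows():
        ok = (not validated_only) or any(
            k in str(r["evidence"]).lower() for k in keywords)
        if ok and r["mirna"] in mirnas:
            targeted.add(r["gene"])
    interacting = set()
    for _, r in ppi.iterrows():
        if r["confidence"] < min_conf or r["protein_a"] == r["protein_b"]:
            continue
        if r["protein_b"] in proteins:
            interacting.add(r["protein_a"])
        if r["protein_a"] in proteins:
            interacting.add(r["protein_b"])
    return targeted & interacting


# -- filters ----------------------------------------------------------------

def test_evidence_filter_keeps_validated_labels():
    edges = targets_df([
        {"mirna": "m1", "gene": "G1", "evidence": "Luciferase reporter assay",
         "source_db": "miRTarBase"},
        {"mirna": "m1", "gene": "G2", "evidence": "Microarray", "source_db": "TarBase"},
        {"mirna": "m1", "gene": "G3", "evidence": "Microarray;Western blot",
         "source_db": "TarBase"},
    ])
    kept = filter_target_edges_by_evidence(edges)
    assert set(kept["gene"]) == {"G1", "G3"}
    assert filter_target_edges_by_evidence(targets_df([])).empty


def test_merge_unions_evidence_across_sources():
    edges = targets_df([
        {"mirna": "m1", "gene": "G1", "evidence": "Microarray", "source_db": "TarBase"},
        {"mirna": "m1", "gene": "G1", "evidence": "qRT-PCR", "source_db": "miRecords"},
    ])
    merged = merge_target_edges(edges)
    assert len(merged) == 1
    assert set(merged.loc[0, "evidence"].split(";")) == {"Microarray", "qRT-PCR"}


def test_confidence_filter_boundary_inclusive(rng):
    edges = ppi_df([
        {"protein_a": "P1", "protein_b": "G1", "confidence": 0.95},
        {"protein_a": "P1", "protein_b": "G2", "confidence": 0.4},
        {"protein_a": "P1", "protein_b": "G3", "confidence": 0.70},
    ])
    kept = filter_ppi_by_confidence(edges)
    assert set(kept["protein_b"]) == {"G1", "G3"}
    rand = ppi_df([{"protein_a": "A", "protein_b": f"N{i}",
                    "confidence": float(c)} for i, c in enumerate(rng.uniform(0, 1, 200))])
    kept = filter_ppi_by_confidence(rand, 0.7)
    assert set(kept["protein_b"]) == {r["protein_b"] for _, r in rand.iterrows()
                                      if r["confidence"] >= 0.7}
    with pytest.raises(ValueError):
        filter_ppi_by_confidence(ppi_df([{"protein_a": "A", "protein_b": "B",
                                          "confidence": 1.4}]))


# -- shells -----------------------------------------------------------------

def test_expand_shells_hand_trace():
    edges = ppi_df([
        {"protein_a": "A", "protein_b": "B", "confidence": 0.9},
        {"protein_a": "A", "protein_b": "C", "confidence": 0.8},
        {"protein_a": "B", "protein_b": "D", "confidence": 0.95},
    ])
    shells = expand_shells({"A"}, edges, InteractomeConfig(max_first_shell=1,
                                                           max_second_shell=1))
    assert shells == {"A": 0, "B": 1, "D": 2}


def test_expand_shells_caps_and_no_padding():
    edges = ppi_df([
        {"protein_a": "A", "protein_b": "B", "confidence": 0.9},
        {"protein_a": "A", "protein_b": "C", "confidence": 0.8},
        {"protein_a": "A", "protein_b": "D", "confidence": 0.85},
    ])
    zero = expand_shells({"A"}, edges, InteractomeConfig(max_first_shell=0,
                                                         max_second_shell=0))
    assert zero == {"A": 0}
    roomy = expand_shells({"A"}, edges, InteractomeConfig())
    assert sum(1 for v in roomy.values() if v == 1) == 3
    assert sum(1 for v in roomy.values() if v == 2) == 0


# -- DAG identification ------------------------------------------------------

def test_identify_dags_toy_case():
    targets = targets_df([
        {"mirna": "m1", "gene": "G1", "evidence": "qRT-PCR", "source_db": "x"},
        {"mirna": "m1", "gene": "G3", "evidence": "Western blot", "source_db": "x"},
    ])
    ppi = ppi_df([{"protein_a": "P1", "protein_b": "G1", "confidence": 0.9}])
    rep = identify_dags(targets, ppi, ["P1", "P2"], ["m1"])
    assert rep.dags == {"G1"}
    assert rep.mirna_only_targets == {"G3"}
    assert rep.n_targeting_mirnas == {"G1": 1}
    assert rep.n_interacting_proteins == {"G1": 1}


def test_proteins_that_are_targets_statistic():
    targets = targets_df([{"mirna": "m1", "gene": "P1",
                           "evidence": "Luciferase reporter assay", "source_db": "x"}])
    rep = identify_dags(targets, ppi_df([]), ["P1", "P2"], ["m1"])
    assert rep.proteins_that_are_targets == ["P1"]
    assert rep.protein_target_overlap == "1 out of 2"


def test_identify_dags_disjoint_layers_empty():
    targets = targets_df([{"mirna": "m1", "gene": "G1",
                           "evidence": "qRT-PCR", "source_db": "x"}])
    ppi = ppi_df([{"protein_a": "P1", "protein_b": "G2", "confidence": 0.9}])
    assert identify_dags(targets, ppi, ["P1"], ["m1"]).dags == set()
    with pytest.raises(ValueError):
        identify_dags(targets, ppi, [], ["m1"])


def test_identify_dags_matches_brute_force_on_random_fixtures(rng):
    mirnas = [f"m{i}" for i in range(8)]
    proteins = [f"P{i}" for i in range(10)]
    evid = ["Luciferase reporter assay", "Western blot", "Microarray", "CLIP-Seq"]
    for _ in range(60):
        genes = [f"G{i}" for i in range(int(rng.integers(5, 60)))]
        t = targets_df([
            {"mirna": mirnas[int(rng.integers(8))], "gene": genes[int(rng.integers(len(genes)))],
             "evidence": evid[int(rng.integers(4))], "source_db": "s"}
            for _ in range(int(rng.integers(1, 80)))])
        p = ppi_df([
            {"protein_a": genes[int(rng.integers(len(genes)))],
             "protein_b": proteins[int(rng.integers(10))],
             "confidence": float(np.round(rng.uniform(0, 1), 3))}
            for _ in range(int(rng.integers(1, 60)))])
        rep = identify_dags(t, p, proteins, mirnas)
        assert rep.dags == brute_force_dags(t, p, set(proteins), set(mirnas))


def test_dag_monotonicity_edge_addition_and_confidence():
    cfg = simulate.SimConfig(seed=3, gene_universe_size=80, n_true_dags=8)
    proteins = [f"P{i:04d}" for i in range(1, 11)]
    mirnas = [f"m{i:04d}" for i in range(1, 9)]
    t, p, _, truth = simulate.gen_interactome(80, proteins, mirnas, 8, cfg)
    base = identify_dags(t, p, proteins, mirnas).dags
    assert base == truth.true_dags
    # adding a validated target edge never shrinks the set
    extra = pd.concat([t, targets_df([{"mirna": mirnas[0], "gene": "G0001",
                                       "evidence": "qRT-PCR", "source_db": "x"}])])
    assert base <= identify_dags(extra, p, proteins, mirnas).dags
    # raising min_confidence never grows it
    strict = identify_dags(t, p, proteins, mirnas,
                           InteractomeConfig(min_confidence=0.9))
    assert strict.dags <= base


def test_evidence_annihilation_empties_dags():
    cfg = simulate.SimConfig(seed=9)
    proteins, mirnas = ["P0001", "P0002"], ["m0001", "m0002"]
    t, p, _, _ = simulate.gen_interactome(40, proteins, mirnas, 4, cfg)
    t = t.assign(evidence="Microarray")
    assert identify_dags(t, p, proteins, mirnas).dags == set()


# -- network ----------------------------------------------------------------

def test_layered_network_partition_and_degrees():
    cfg = simulate.SimConfig(seed=13)
    proteins = [f"P{i:04d}" for i in range(1, 9)]
    mirnas = [f"m{i:04d}" for i in range(1, 7)]
    t, p, _, _ = simulate.gen_interactome(60, proteins, mirnas, 6, cfg)
    rep = identify_dags(t, p, proteins, mirnas)
    net = build_layered_network(rep, t, p, proteins, mirnas)
    layers = {}
    for node, data in net.nodes(data=True):
        layers.setdefault(data["layer"], set()).add(node)
    assert sum(len(v) for v in layers.values()) == net.number_of_nodes()
    for dag in layers.get("dag", set()):
        types = {net.edges[e]["type"] for e in net.edges(dag)}
        assert types == {"targets", "interacts"}
    for node in layers.get("mirna_only_target", set()):
        assert {net.edges[e]["type"] for e in net.edges(node)} <= {"targets"}


def test_network_without_target_edges_has_two_layers():
    ppi = ppi_df([{"protein_a": "P1", "protein_b": "P2", "confidence": 0.9}])
    rep = identify_dags(targets_df([]), ppi, ["P1", "P2"], ["m1"])
    net = build_layered_network(rep, targets_df([]), ppi, ["P1", "P2"], ["m1"])
    assert {d["layer"] for _, d in net.nodes(data=True)} == {"exosomal_protein", "mirna"}


def test_graphml_roundtrip_and_sif(tmp_path):
    cfg = simulate.SimConfig(seed=2)
    proteins, mirnas = ["P0001", "P0002", "P0003"], ["m0001", "m0002"]
    t, p, _, _ = simulate.gen_interactome(30, proteins, mirnas, 3, cfg)
    rep = identify_dags(t, p, proteins, mirnas)
    net = build_layered_network(rep, t, p, proteins, mirnas)
    gpath = tmp_path / "net.graphml"
    export_network(net, gpath)
    back = read_graphml(gpath)
    assert set(back.nodes) == set(net.nodes)
    assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in net.edges}
    assert all(back.nodes[n]["layer"] == net.nodes[n]["layer"] for n in net.nodes)
    spath = tmp_path / "net.sif"
    export_network(net, spath)
    assert len(spath.read_text().splitlines()) == net.number_of_edges()
    with pytest.raises(ValueError):
        export_network(net, tmp_path / "net.xyz")


# -- grouping and disease ranking -------------------------------------------

def test_multiplicity_groups_distinct_rule():
    t = targets_df([
        {"mirna": "m1", "gene": "G1", "evidence": "e", "source_db": "s"},
        {"mirna": "m2", "gene": "G1", "evidence": "e", "source_db": "s"},
        {"mirna": "m3", "gene": "G1", "evidence": "e", "source_db": "s"},
        {"mirna": "m1", "gene": "G2", "evidence": "e", "source_db": "s"},
        {"mirna": "m1", "gene": "G2", "evidence": "e2", "source_db": "s2"},
        {"mirna": "m1", "gene": "G3", "evidence": "e", "source_db": "s"},
        {"mirna": "m2", "gene": "G3", "evidence": "e", "source_db": "s"},
    ])
    groups = group_genes_by_mirna_multiplicity(t, ["m1", "m2", "m3"])
    assert groups[">=3"] == {"G1"}
    assert groups["1"] == {"G2"}  # duplicate edges count once
    assert groups["2"] == {"G3"}


def test_multiplicity_matches_brute_force(rng):
    mirnas = [f"m{i}" for i in range(6)]
    rows = [{"mirna": mirnas[int(rng.integers(6))], "gene": f"G{int(rng.integers(20))}",
             "evidence": "e", "source_db": "s"} for _ in range(150)]
    t = targets_df(rows)
    groups = group_genes_by_mirna_multiplicity(t, mirnas)
    degree = {}
    for r in rows:
        degree.setdefault(r["gene"], set()).add(r["mirna"])
    for g, ms in degree.items():
        key = "1" if len(ms) == 1 else "2" if len(ms) == 2 else ">=3"
        assert g in groups[key]


def test_disease_ranking_tie_break_and_defaults():
    table = {"ERBB2": 32, "CD44": 32, "SPP1": 20}
    ranked = rank_by_disease_publications(["SPP1", "ERBB2", "CD44", "APOE"], table)
    assert ranked == [("CD44", 32), ("ERBB2", 32), ("SPP1", 20), ("APOE", 0)]
    assert rank_by_disease_publications(["x"], {}) == [("x", 0)]
    with pytest.raises(ValueError):
        rank_by_disease_publications(["x"], {"x": -1})
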