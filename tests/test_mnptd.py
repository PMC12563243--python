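"""Unit and property tests for the multi-dimensional gene prioritizer."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnsrepurpose import mnptd
from cnsrepurpose.mnptd import (
    CentralityProfile,
    GeneFeatureFlags,
    PathwayAnnotation,
    adaptive_integrate,
    bootstrap_stability,
    compute_centralities,
    disease_proximity,
    druggability_score,
    pathway_centrality_index,
    permutation_significance,
    plasticity_score,
    score_genes,
    temporal_final_score,
)


def _profile(**kwargs) -> CentralityProfile:
    defaults = dict(
        gene="X", degree=1, degree_centrality=0.0, betweenness=0.0,
        closeness=0.0, eigenvector=0.0,
    )
    defaults.update(kwargs)
    return CentralityProfile(**defaults)


# --------------------------------------------------------------------------
# centralities
# --------------------------------------------------------------------------

def test_path_center_has_unit_centralities(path_graph_abc):
    profiles = {p.gene: p for p in compute_centralities(path_graph_abc)}
    b = profiles["B"]
    assert b.degree == 2
    assert b.degree_centrality == pytest.approx(1.0)
    assert b.betweenness == pytest.approx(1.0)
    assert b.closeness == pytest.approx(1.0)
    assert b.eigenvector == pytest.approx(1.0 / math.sqrt(2), abs=1e-6)


def test_path_leaves_are_symmetric(path_graph_abc):
    profiles = {p.gene: p for p in compute_centralities(path_graph_abc)}
    a, c = profiles["A"], profiles["C"]
    for attr in ("degree_centrality", "betweenness", "closeness", "eigenvector"):
        assert getattr(a, attr) == pytest.approx(getattr(c, attr))
    assert a.betweenness == pytest.approx(0.0)


def test_empty_network_rejected():
    with pytest.raises(ValueError, match="empty network"):
        compute_centralities(nx.Graph())


def test_self_loops_rejected():
    g = nx.Graph()
    g.add_edge("A", "A")
    with pytest.raises(ValueError, match="self-loops"):
        compute_centralities(g)


def test_eigenvector_zero_off_largest_component():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    g.add_node("LONE")
    profiles = {p.gene: p for p in compute_centralities(g)}
    assert profiles["LONE"].eigenvector == 0.0
    assert profiles["B"].eigenvector > 0.0


def test_single_node_graph_carries_unit_eigenvector():
    g = nx.Graph()
    g.add_node("ONLY")
    (p,) = compute_centralities(g)
    assert p.eigenvector == pytest.approx(1.0)
    assert p.degree == 0


# --------------------------------------------------------------------------
# plasticity
# --------------------------------------------------------------------------

def test_plasticity_of_path_center(path_graph_abc):
    b = {p.gene: p for p in compute_centralities(path_graph_abc)}["B"]
    di, ci, ni, pi = plasticity_score(b)
    assert di == pytest.approx(1.0)
    assert ci == pytest.approx(0.0)
    assert ni == pytest.approx(0.7071, abs=1e-4)
    assert pi == pytest.approx(0.5690, abs=1e-4)


def test_plasticity_hand_arithmetic():
    p = _profile(degree=4, degree_centrality=0.5, betweenness=0.2,
                 closeness=0.5, eigenvector=0.3)
    di, ci, ni, pi = plasticity_score(p)
    assert di == pytest.approx(0.1)
    assert ci == pytest.approx(2.0)
    assert ni == pytest.approx(0.03)
    assert pi == pytest.approx(0.71)


def test_hub_plasticity_driven_by_raw_degree():
    # the clustering-disruption term uses raw degree, so a 20-edge hub with
    # moderate closeness dwarfs a 2-edge node with identical normalized values
    hub = _profile(degree=20, degree_centrality=0.4, betweenness=0.3,
                   closeness=0.5, eigenvector=0.5)
    small = _profile(degree=2, degree_centrality=0.4, betweenness=0.3,
                     closeness=0.5, eigenvector=0.5)
    assert plasticity_score(hub)[3] > plasticity_score(small)[3]


# --------------------------------------------------------------------------
# pathway centrality index
# --------------------------------------------------------------------------

def test_pci_single_record():
    ann = [PathwayAnnotation("G", "PW1", "GO_BP", 0.1)]
    pd_, ps, pc, ws, pci = pathway_centrality_index(ann)
    assert (pd_, ps, pc, ws) == (1.0, 1.0, 1.0, 1.0)
    assert pci == pytest.approx(1.0)


def test_pci_two_database_example():
    ann = [
        PathwayAnnotation("G", "PW1", "GO_BP", 1e-3),
        PathwayAnnotation("G", "PW2", "KEGG", 1e-5),
    ]
    pd_, ps, pc, ws, pci = pathway_centrality_index(ann)
    assert pd_ == 2.0
    assert ps == pytest.approx(4.0)
    assert pc == 2.0
    assert ws == pytest.approx((1.0 * 3 + 0.8 * 5) / 2)
    assert pci == pytest.approx(3.1)


def test_pci_no_annotations_scores_zero():
    assert pathway_centrality_index([]) == (0.0, 0.0, 0.0, 0.0, 0.0)


def test_pathway_annotation_validation():
    with pytest.raises(ValueError, match="unknown db_type"):
        PathwayAnnotation("G", "PW", "NOTADB", 0.01)
    with pytest.raises(ValueError, match="adj_p"):
        PathwayAnnotation("G", "PW", "KEGG", 0.0)
    with pytest.raises(ValueError, match="adj_p"):
        PathwayAnnotation("G", "PW", "KEGG", 1.5)


# --------------------------------------------------------------------------
# druggability and disease proximity
# --------------------------------------------------------------------------

def test_druggability_receptor_like_gene():
    flags = GeneFeatureFlags(
        gene="G", is_membrane=True, is_ion_channel=True,
        is_neurotransmitter=True, base_druggability=0.15,
    )
    assert druggability_score(flags) == pytest.approx(0.80)


def test_druggability_capped_at_one():
    flags = GeneFeatureFlags(
        gene="G", is_membrane=True, is_enzyme=True, is_gpcr=True,
        is_ion_channel=True, is_neurotransmitter=True, base_druggability=0.3,
    )
    assert druggability_score(flags) == 1.0


def test_druggability_defaults_by_known_target_status():
    known = GeneFeatureFlags(gene="G", is_known_ad_target=True)
    novel = GeneFeatureFlags(gene="G")
    assert druggability_score(known) == pytest.approx(0.3)
    assert druggability_score(novel) == pytest.approx(0.1)


def test_druggability_invalid_base_rejected():
    with pytest.raises(ValueError, match="base_druggability"):
        druggability_score(GeneFeatureFlags(gene="G", base_druggability=1.2))


def test_disease_proximity_saturated_known_gene():
    flags = GeneFeatureFlags(gene="G", is_known_ad_target=True, ad_pathway_overlap=12)
    prof = _profile(degree_centrality=1.0, betweenness=1.0, eigenvector=1.0)
    cp, pp, fp, dp = disease_proximity(flags, prof)
    assert (cp, pp, fp) == (1.0, 1.0, pytest.approx(0.8))
    assert dp == pytest.approx(0.98)


def test_disease_proximity_hand_arithmetic():
    flags = GeneFeatureFlags(gene="G", direct_ad_association=0.5, ad_pathway_overlap=5)
    prof = _profile(degree_centrality=0.2, betweenness=0.1, eigenvector=0.3)
    cp, pp, fp, dp = disease_proximity(flags, prof)
    assert cp == pytest.approx(0.2)
    assert pp == pytest.approx(0.5)
    assert fp == pytest.approx(0.4)
    assert dp == pytest.approx(0.40)


# --------------------------------------------------------------------------
# adaptive integration and temporal weighting
# --------------------------------------------------------------------------

def test_adaptive_weights_without_triggers_stay_uniform():
    w, _ = adaptive_integrate(0.2, 0.5, 0.4, 0.3)
    assert np.allclose(w, 0.25)


def test_adaptive_weights_membrane_only_trigger():
    w, _ = adaptive_integrate(0.4, 0.9, 1.0, 1.0, is_membrane=True)
    assert np.allclose(w, np.array([0.25, 0.25, 0.375, 0.25]) / 1.125)


def test_adaptive_integration_hand_arithmetic():
    w, integrated = adaptive_integrate(0.6, 1.2, 0.8, 0.4, is_membrane=True)
    assert np.allclose(w, [0.26, 0.24, 0.30, 0.20])
    assert integrated == pytest.approx(0.764)


@given(
    plasticity=st.floats(0.0, 20.0),
    pci=st.floats(0.0, 10.0),
    druggability=st.floats(0.0, 1.0),
    proximity=st.floats(0.0, 1.0),
    membrane=st.booleans(),
)
def test_adaptive_weights_always_renormalize(plasticity, pci, druggability, proximity, membrane):
    w, integrated = adaptive_integrate(
        plasticity, pci, druggability, proximity, is_membrane=membrane
    )
    assert w.sum() == pytest.approx(1.0)
    assert (w > 0).all()
    scores = [plasticity, pci, druggability, proximity]
    assert min(scores) - 1e-12 <= integrated <= max(scores) + 1e-12


def test_temporal_weighting_scales_integrated_score():
    tw, fs = temporal_final_score(10.0, "symptomatic")
    assert tw == 0.6
    assert fs == pytest.approx(6.0)
    assert temporal_final_score(1.0, "early_intervention") == (1.0, 1.0)


def test_unknown_temporal_category_rejected():
    with pytest.raises(ValueError, match="unknown temporal category"):
        temporal_final_score(1.0, "late")
    with pytest.raises(ValueError, match="unknown temporal category"):
        GeneFeatureFlags(gene="G", temporal_category="late")


# --------------------------------------------------------------------------
# full gene scoring
# --------------------------------------------------------------------------

def test_score_genes_table_shape_and_ranking(path_graph_abc):
    flags = [GeneFeatureFlags(gene="B", is_membrane=True, is_known_ad_target=True,
                              temporal_category="early_intervention")]
    ann = [PathwayAnnotation("B", "PW", "GO_BP", 1e-4)]
    table = score_genes(path_graph_abc, ann, flags)
    assert list(table["rank"]) == [1, 2, 3]
    assert table["final_score"].is_monotonic_decreasing
    assert table.iloc[0]["gene"] == "B"
    for col in ("plasticity", "pci", "druggability", "disease_proximity",
                "integrated", "temporal_weight", "final_score", "is_membrane"):
        assert col in table.columns


def test_score_genes_breaks_ties_lexicographically():
    # a 4-cycle is vertex-transitive, so every gene scores identically
    g = nx.relabel_nodes(nx.cycle_graph(4), dict(enumerate("ABCD")))
    table = score_genes(g, [], [])
    scores = table.set_index("gene")["final_score"]
    assert scores["A"] == scores["B"] == scores["C"] == scores["D"]
    assert list(table["gene"]) == ["A", "B", "C", "D"]


def test_score_genes_deterministic(path_graph_abc):
    t1 = score_genes(path_graph_abc, [], [])
    t2 = score_genes(path_graph_abc, [], [])
    pd.testing.assert_frame_equal(t1, t2)


# --------------------------------------------------------------------------
# permutation significance
# --------------------------------------------------------------------------

def _toy_table(n: int, planted_score: float | None = None, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.0, 1.0, size=(n, 4))
    if planted_score is not None:
        scores[0] = planted_score
    membrane = rng.random(n) < 0.3
    tw = np.full(n, 1.0)
    final = mnptd._integrate_matrix(scores, membrane, tw)
    return pd.DataFrame(
        {
            "gene": [f"G{i}" for i in range(n)],
            "plasticity": scores[:, 0],
            "pci": scores[:, 1],
            "druggability": scores[:, 2],
            "disease_proximity": scores[:, 3],
            "is_membrane": membrane,
            "temporal_weight": tw,
            "final_score": final,
        }
    )


def test_permutation_flags_planted_outlier():
    table = _toy_table(100, planted_score=100.0)
    out = permutation_significance(table, n_perm=200, seed=1)
    assert bool(out.loc[out["gene"] == "G0", "significant_95"].iloc[0])
    assert out.loc[out["gene"] == "G0", "permutation_p"].iloc[0] < 0.05


def test_permutation_identical_scores_never_significant():
    n = 20
    table = _toy_table(n)
    for col in ("plasticity", "pci", "druggability", "disease_proximity"):
        table[col] = 0.5
    table["is_membrane"] = False
    table["final_score"] = mnptd._integrate_matrix(
        np.full((n, 4), 0.5), np.zeros(n, bool), table["temporal_weight"].to_numpy()
    )
    out = permutation_significance(table, n_perm=200, seed=1)
    assert not out["significant_95"].any()


def test_permutation_validates_inputs():
    table = _toy_table(10)
    with pytest.raises(ValueError, match="insufficient permutations"):
        permutation_significance(table, n_perm=50)
    with pytest.raises(ValueError, match="at least 2 genes"):
        permutation_significance(table.iloc[:1], n_perm=200)


def test_integrate_matrix_matches_scalar_path():
    table = _toy_table(25, seed=3)
    scores = table[["plasticity", "pci", "druggability", "disease_proximity"]].to_numpy()
    membrane = table["is_membrane"].to_numpy(dtype=bool)
    vec = mnptd._integrate_matrix(scores, membrane, np.ones(25))
    for i in range(25):
        _, integrated = adaptive_integrate(*scores[i], is_membrane=bool(membrane[i]))
        assert vec[i] == pytest.approx(integrated)


# --------------------------------------------------------------------------
# bootstrap stability
# --------------------------------------------------------------------------

def test_bootstrap_deterministic_scores_have_zero_cv():
    table = _toy_table(30, seed=5)
    out = bootstrap_stability(table, top_k=5, n_boot=100, seed=2)
    assert np.allclose(out["score_cv"], 0.0, atol=1e-6)


def test_bootstrap_dominant_gene_always_in_topk():
    table = _toy_table(30, planted_score=50.0, seed=5)
    table["final_score"] = mnptd._integrate_matrix(
        table[["plasticity", "pci", "druggability", "disease_proximity"]].to_numpy(),
        table["is_membrane"].to_numpy(bool),
        table["temporal_weight"].to_numpy(),
    )
    out = bootstrap_stability(table, top_k=5, n_boot=200, seed=2)
    assert out.loc[out["gene"] == "G0", "topk_frequency"].iloc[0] == pytest.approx(1.0)


def test_bootstrap_topk_exceeding_n_rejected():
    with pytest.raises(ValueError, match="top_k"):
        bootstrap_stability(_toy_table(5), top_k=6, n_boot=100)
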