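"""Multi-layer pharmacogenomic network construction and propagation scoring.

Builds a bipartite drug-gene interaction layer plus Jaccard-similarity
drug-drug and gene-gene layers, integrates them into one graph, and scores
each drug against a target-gene set by random walk with restart, shortest-path
proximity, and direct-interaction evidence, combined with fixed 0.4/0.3/0.3
weights. A multi-criteria CNS pre-filter restricts the drug universe to
compounds with plausible neurological relevance before network construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "DrugRecord",
    "InteractionRecord",
    "CNSFilterConfig",
    "RWRConfig",
    "LayeredNetwork",
    "canonical_drug_name",
    "drug_node",
    "gene_node",
    "cns_filter",
    "jaccard",
    "build_layers",
    "topology_summary",
    "rwr",
    "subsample_for_rwr",
    "proximity_scores",
    "direct_interaction_score",
    "combined_score",
    "diffusion_proximity",
    "resistance_distance",
    "retention_percentage",
    "score_drugs",
]

#: Default imputed weight for interactions lacking a confidence score.
MISSING_SCORE_DEFAULT = 0.5

#: Combined-score weights over (rwr, proximity, direct interaction).
COMBINED_WEIGHTS = (0.4, 0.3, 0.3)


def canonical_drug_name(name: str) -> str:
    """Uppercase, trim, and collapse internal whitespace."""
    return re.sub(r"\s+", " ", name.strip()).upper()


def drug_node(name: str) -> tuple[str, str]:
    """Namespaced node id for a drug (avoids collisions with gene symbols)."""
    return ("drug", canonical_drug_name(name))


def gene_node(symbol: str) -> tuple[str, str]:
    return ("gene", symbol)


@dataclass(frozen=True)
class DrugRecord:
    name: str
    approved: bool = False
    source_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", canonical_drug_name(self.name))


@dataclass(frozen=True)
class InteractionRecord:
    """A drug-gene interaction; missing scores are imputed to 0.5."""

    drug: str
    gene: str
    score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", canonical_drug_name(self.drug))

    @property
    def weight(self) -> float:
        return MISSING_SCORE_DEFAULT if self.score is None else self.score


@dataclass
class CNSFilterConfig:
    """Four complementary CNS-relevance criteria; a drug passing any is kept."""

    name_keywords: list[str] = field(
        default_factory=lambda: [
            "neuro",
            "brain",
            "cognitive",
            "psychiatric",
            "anticonvulsant",
            "analgesic",
            "antipsychotic",
        ]
    )
    curated_cns_drugs: list[str] = field(default_factory=list)
    neuro_gene_keywords: list[str] = field(
        default_factory=lambda: [
            "GABR",
            "GRIN",
            "GRIA",
            "DRD",
            "HTR",
            "CHRN",
            "CHRM",
            "APP",
            "PSEN",
            "APOE",
            "SNCA",
            "LRRK2",
            "MAOA",
            "COMT",
            "SLC6A3",
            "SLC6A4",
        ]
    )
    include_all_approved: bool = True


@dataclass
class RWRConfig:
    """Random-walk-with-restart parameters."""

    restart_alpha: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000
    max_subgraph_nodes: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_alpha < 1.0:
            raise ValueError("restart_alpha must be in (0, 1)")
        if self.tol <= 0 or self.max_iter <= 0 or self.max_subgraph_nodes <= 0:
            raise ValueError("tol, max_iter and max_subgraph_nodes must be positive")


@dataclass
class LayeredNetwork:
    """Bipartite drug-gene layer plus similarity layers and their union."""

    bipartite: nx.Graph
    drug_drug: nx.Graph
    gene_gene: nx.Graph
    integrated: nx.Graph


def cns_filter(
    drugs: list[DrugRecord],
    interactions: list[InteractionRecord],
    cfg: CNSFilterConfig,
) -> pd.DataFrame:
    """Retain drugs passing any of the four CNS-relevance criteria.

    Returns one row per retained drug with boolean provenance columns saying
    which criteria fired: name-keyword match (case-insensitive substring),
    curated-list membership, interaction with a neuro-keyword gene, or FDA
    approval when ``include_all_approved`` is set.
    """
    if not drugs:
        raise ValueError("empty drug list")
    curated = {canonical_drug_name(d) for d in cfg.curated_cns_drugs}
    targets_by_drug: dict[str, set[str]] = {}
    for rec in interactions:
        targets_by_drug.setdefault(rec.drug, set()).add(rec.gene)
    gene_keys = [k.upper() for k in cfg.neuro_gene_keywords]

    rows = []
    for drug in drugs:
        by_name = any(kw.upper() in drug.name for kw in cfg.name_keywords)
        by_curated = drug.name in curated
        by_target = any(
            any(key in gene.upper() for key in gene_keys)
            for gene in targets_by_drug.get(drug.name, ())
        )
        by_approved = cfg.include_all_approved and drug.approved
        if by_name or by_curated or by_target or by_approved:
            rows.append(
                {
                    "drug": drug.name,
                    "approved": drug.approved,
                    "by_name_keyword": by_name,
                    "by_curated_list": by_curated,
                    "by_neuro_target": by_target,
                    "by_approved": by_approved,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "approved",
            "by_name_keyword",
            "by_curated_list",
            "by_neuro_target",
            "by_approved",
        ],
    )


def retention_percentage(n_kept: int, n_total: int) -> float:
    """Filter retention as a percentage, reported to one decimal place."""
    if n_total <= 0:
        raise ValueError("total drug count must be positive")
    if not 0 <= n_kept <= n_total:
        raise ValueError("kept count must be between 0 and the total")
    return round(100.0 * n_kept / n_total, 1)


def jaccard(set_a: set, set_b: set) -> float:
    """Jaccard similarity |A&B|/|A|B|; defined as 0 when both sets are empty."""
    if not set_a and not set_b:
        return 0.0
    return len(set_a & set_b) / len(set_a | set_b)


def build_layers(
    drugs: list[str],
    genes: list[str],
    interactions: list[InteractionRecord],
    sim_threshold: float = 0.15,
    min_interactions: int = 0,
    max_drugs: int | None = None,
    max_genes: int | None = None,
) -> LayeredNetwork:
    """Construct the three network layers and their integrated union.

    Bipartite edges carry the interaction score (0.5 where missing); the
    similarity layers connect drug pairs (gene pairs) whose Jaccard similarity
    over shared targets (shared interacting drugs) is at least
    ``sim_threshold``. Optional frequency/connectivity caps restrict the node
    universe before construction; they are off by default.
    """
    drug_names = [canonical_drug_name(d) for d in drugs]
    known_drugs = set(drug_names)
    known_genes = set(genes)
    for rec in interactions:
        if rec.drug not in known_drugs:
            raise ValueError(f"interaction references unknown drug {rec.drug!r}")
        if rec.gene not in known_genes:
            raise ValueError(f"interaction references unknown gene {rec.gene!r}")

    targets: dict[str, set[str]] = {d: set() for d in drug_names}
    binders: dict[str, set[str]] = {g: set() for g in genes}
    for rec in interactions:
        targets[rec.drug].add(rec.gene)
        binders[rec.gene].add(rec.drug)

    if min_interactions > 0:
        drug_names = [d for d in drug_names if len(targets[d]) >= min_interactions]
        genes = [g for g in genes if len(binders[g]) >= min_interactions]
    if max_drugs is not None:
        drug_names = sorted(drug_names, key=lambda d: (-len(targets[d]), d))[:max_drugs]
    if max_genes is not None:
        genes = sorted(genes, key=lambda g: (-len(binders[g]), g))[:max_genes]
    kept_drugs, kept_genes = set(drug_names), set(genes)

    bipartite = nx.Graph()
    bipartite.add_nodes_from(drug_node(d) for d in drug_names)
    bipartite.add_nodes_from(gene_node(g) for g in genes)
    for rec in interactions:
        if rec.drug in kept_drugs and rec.gene in kept_genes:
            bipartite.add_edge(drug_node(rec.drug), gene_node(rec.gene), weight=rec.weight)

    def _similarity_layer(items, profiles, node_fn) -> nx.Graph:
        layer = nx.Graph()
        layer.add_nodes_from(node_fn(x) for x in items)
        ordered = sorted(items)
        for i, a in enumerate(ordered):
            pa = profiles[a]
            if not pa:
                continue
            for b in ordered[i + 1 :]:
                sim = jaccard(pa, profiles[b])
                if sim >= sim_threshold:
                    layer.add_edge(node_fn(a), node_fn(b), weight=sim)
        return layer

    drug_drug = _similarity_layer(drug_names, targets, drug_node)
    gene_gene = _similarity_layer(genes, binders, gene_node)

    integrated = nx.Graph()
    for layer in (bipartite, drug_drug, gene_gene):
        integrated.add_nodes_from(layer.nodes())
        integrated.add_edges_from(layer.edges(data=True))
    return LayeredNetwork(bipartite, drug_drug, gene_gene, integrated)


def topology_summary(
    graph: nx.Graph, sample_pairs: int = 1000, seed: int = 42
) -> dict[str, float]:
    """Summary topology statistics with sampled average path length.

    Average path length is estimated over ``sample_pairs`` random node pairs,
    averaging shortest-path lengths of the reachable ones; deterministic for a
    fixed seed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    components = list(nx.connected_components(graph))
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes(), key=str)
    lengths = []
    if n > 1:
        for _ in range(sample_pairs):
            i, j = rng.choice(n, size=2, replace=False)
            try:
                lengths.append(nx.shortest_path_length(graph, nodes[i], nodes[j]))
            except nx.NetworkXNoPath:
                continue
    return {
        "nodes": n,
        "edges": e,
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        "n_components": len(components),
        "largest_component": max(len(c) for c in components),
        "avg_clustering": nx.average_clustering(graph),
        "transitivity": nx.transitivity(graph),
        "sampled_avg_path_length": float(np.mean(lengths)) if lengths else float("nan"),
    }


def _transition_matrix(graph: nx.Graph, nodes: list) -> tuple[sp.csr_matrix, np.ndarray]:
    """Column-normalized weighted adjacency and dangling-column mask."""
    a = nx.to_scipy_sparse_array(
        graph, nodelist=nodes, weight="weight", format="csc"
    ).astype(float)
    col_sums = np.asarray(a.sum(axis=0), dtype=float).ravel()
    dangling = col_sums == 0
    inv = np.zeros_like(col_sums)
    inv[~dangling] = 1.0 / col_sums[~dangling]
    p = (a @ sp.diags(inv)).tocsr()
    return p, dangling


def rwr(graph: nx.Graph, seed_nodes: set, cfg: RWRConfig | None = None) -> dict:
    """Random walk with restart: steady-state visiting probability per node.

    Iterates ``p <- (1-alpha) P p + alpha p0`` with the column-normalized
    weighted adjacency P and a uniform restart vector over the seed nodes,
    until the L1 change falls below ``tol``. Degree-zero (dangling) nodes
    teleport their mass back to the restart distribution, so the result is a
    probability vector summing to one.
    """
    cfg = cfg or RWRConfig()
    nodes = sorted(graph.nodes(), key=str)
    index = {node: i for i, node in enumerate(nodes)}
    seeds = [index[s] for s in seed_nodes if s in index]
    if not seeds:
        raise ValueError("empty seed set")
    p0 = np.zeros(len(nodes))
    p0[seeds] = 1.0 / len(seeds)
    if len(nodes) == 1:
        return {nodes[0]: 1.0}
    pmat, dangling = _transition_matrix(graph, nodes)
    alpha = cfg.restart_alpha
    p = p0.copy()
    for _ in range(cfg.max_iter):
        dangling_mass = p[dangling].sum()
        p_next = (1 - alpha) * (pmat @ p + dangling_mass * p0) + alpha * p0
        if np.abs(p_next - p).sum() < cfg.tol:
            p = p_next
            break
        p = p_next
    return dict(zip(nodes, p))


def subsample_for_rwr(graph: nx.Graph, target_genes: set, max_nodes: int) -> nx.Graph:
    """Breadth-first neighborhood subgraph around the target genes.

    All targets are included, then successive hop shells are added (node ids
    sorted lexicographically within a shell) until ``max_nodes`` is reached.
    Graphs already within the budget are returned whole.
    """
    present = [t for t in sorted(target_genes, key=str) if t in graph]
    if max_nodes < len(present):
        raise ValueError("max_nodes smaller than the number of target genes")
    if graph.number_of_nodes() <= max_nodes:
        return graph
    selected: list = list(present)
    chosen = set(present)
    frontier = list(present)
    while frontier and len(selected) < max_nodes:
        nxt = sorted(
            {nbr for node in frontier for nbr in graph.neighbors(node)} - chosen,
            key=str,
        )
        for node in nxt:
            if len(selected) >= max_nodes:
                break
            selected.append(node)
            chosen.add(node)
        frontier = [node for node in nxt if node in chosen]
    return graph.subgraph(selected).copy()


def proximity_scores(
    graph: nx.Graph, drug, target_genes: list
) -> tuple[float, float]:
    """Average shortest-path distance to the targets and its inverse score.

    Unreachable drug-target pairs are assigned a finite penalty distance equal
    to the node count of the graph, keeping the proximity score defined while
    strictly penalizing disconnection. Returns ``(avg_distance, 1/(1+avg))``.
    """
    if drug not in graph:
        raise ValueError(f"drug {drug!r} not in network")
    if not target_genes:
        raise ValueError("no target genes")
    penalty = graph.number_of_nodes()
    sp_from_drug = nx.single_source_shortest_path_length(graph, drug)
    dists = [sp_from_drug.get(g, penalty) for g in target_genes]
    d_sp = float(np.mean(dists))
    return d_sp, 1.0 / (1.0 + d_sp)


def direct_interaction_score(
    drug: str, target_genes: list[str], interactions: list[InteractionRecord]
) -> float:
    """Mean interaction weight over targets, zero where no edge is recorded."""
    if not target_genes:
        raise ValueError("no target genes")
    name = canonical_drug_name(drug)
    weights = {(rec.drug, rec.gene): rec.weight for rec in interactions}
    return float(np.mean([weights.get((name, g), 0.0) for g in target_genes]))


def combined_score(
    rwr_score: float,
    proximity: float,
    direct: float,
    weights: tuple[float, float, float] = COMBINED_WEIGHTS,
) -> float:
    """Weighted combination of the three scoring dimensions (default 0.4/0.3/0.3)."""
    return weights[0] * rwr_score + weights[1] * proximity + weights[2] * direct


def diffusion_proximity(
    graph: nx.Graph, drug, target_genes: set, cfg: RWRConfig | None = None
) -> float:
    """Diffusion score: restart-0.5 walk seeded at the targets, read at the drug.

    Reported alongside the main scores; it does not enter the combined score.
    """
    base = cfg or RWRConfig()
    diffuse_cfg = RWRConfig(
        restart_alpha=0.5,
        tol=base.tol,
        max_iter=base.max_iter,
        max_subgraph_nodes=base.max_subgraph_nodes,
    )
    probs = rwr(graph, target_genes, diffuse_cfg)
    return probs.get(drug, 0.0)


def resistance_distance(graph: nx.Graph, node_a, node_b) -> float:
    """Effective resistance between two nodes via the Laplacian pseudoinverse.

    Restricted to graphs of at most 2000 nodes (dense pseudoinverse); both
    nodes must lie in the same connected component.
    """
    if graph.number_of_nodes() > 2000:
        raise ValueError("resistance distance restricted to graphs with <= 2000 nodes")
    return nx.resistance_distance(graph, node_a, node_b)


def score_drugs(
    layers: LayeredNetwork,
    drugs: list[str],
    target_genes: list[str],
    interactions: list[InteractionRecord],
    cfg: RWRConfig | None = None,
) -> pd.DataFrame:
    """Score every drug against the target-gene set on the integrated network.

    Runs one restart walk seeded at the targets (on a breadth-first subsample
    when the integrated graph exceeds the configured node budget), then adds
    shortest-path proximity and direct-interaction evidence per drug, the
    combined score, and the side-output diffusion proximity.
    """
    cfg = cfg or RWRConfig()
    graph = layers.integrated
    target_nodes = {gene_node(g) for g in target_genes if gene_node(g) in graph}
    if not target_nodes:
        raise ValueError("empty seed set")
    work = subsample_for_rwr(graph, target_nodes, cfg.max_subgraph_nodes)
    rwr_probs = rwr(work, target_nodes, cfg)
    diffusion = rwr(
        work,
        target_nodes,
        RWRConfig(0.5, cfg.tol, cfg.max_iter, cfg.max_subgraph_nodes),
    )
    rows = []
    for name in sorted(canonical_drug_name(d) for d in drugs):
        node = drug_node(name)
        if node not in graph:
            continue
        s_rwr = rwr_probs.get(node, 0.0)
        if node in work:
            d_sp, s_np = proximity_scores(work, node, sorted(target_nodes, key=str))
        else:
            d_sp = float(graph.number_of_nodes())
            s_np = 1.0 / (1.0 + d_sp)
        s_di = direct_interaction_score(name, target_genes, interactions)
        rows.append(
            {
                "drug": name,
                "rwr": s_rwr,
                "avg_sp_distance": d_sp,
                "proximity": s_np,
                "direct": s_di,
                "combined": combined_score(s_rwr, s_np, s_di),
                "diffusion": diffusion.get(node, 0.0),
            }
        )
    return pd.DataFrame(rows)
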