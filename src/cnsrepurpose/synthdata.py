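"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its configuration: identical seeds give
byte-identical outputs. The generators emulate the statistical shape the
analysis assumes — a scale-free protein-interaction network with a densely
wired disease module, Poisson multi-database pathway annotations enriched in
the module, a sparse bipartite drug-gene interaction table with a configurable
fraction of missing confidence scores, physicochemical property tables drawn
from truncated normals centered on CNS-like summary statistics, and a
two-class labeled descriptor set for supervised barrier-penetration
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .mnptd import GeneFeatureFlags, PathwayAnnotation, TEMPORAL_WEIGHTS
from .netmed import InteractionRecord, DrugRecord

__all__ = [
    "SyntheticConfig",
    "gen_drug_names",
    "gen_drug_records",
    "gen_ppi_network",
    "gen_pathway_table",
    "gen_flags_table",
    "gen_interactions",
    "gen_property_table",
    "gen_bbb_validation",
]

_DB_TYPES = ["GO_BP", "KEGG", "Reactome", "GO_MF", "Hallmark"]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults reflect a desk-scale version of the analyzed data: a ~500-gene
    scale-free interaction network, a 20-gene disease module, 300 drugs of
    which 5 are planted true positives wired into the module, half of the
    drugs approved, 10% of interaction scores missing (imputed downstream to
    0.5), small-molecule property distributions centered on MW 317.8 +/- 77.4
    Da, LogP 2.18 +/- 0.96, PSA 52.3 +/- 20.2 A^2, and a 70/40 two-class
    barrier-penetration set separated by 3 standardized units.
    """

    seed: int = 42
    n_genes: int = 500
    n_drugs: int = 300
    attachment_m: int = 2
    n_target_genes: int = 20
    n_planted_drugs: int = 5
    approved_fraction: float = 0.5
    missing_score_fraction: float = 0.1
    exact_edges: int | None = None
    peptide_fraction: float = 0.02
    biologic_fraction: float = 0.01
    property_means: dict = field(
        default_factory=lambda: {"mw": 317.8, "logp": 2.18, "psa": 52.3, "hbd": 1.4, "hba": 3.2}
    )
    property_sds: dict = field(
        default_factory=lambda: {"mw": 77.4, "logp": 0.96, "psa": 20.2, "hbd": 1.1, "hba": 2.0}
    )
    n_bbb_positive: int = 70
    n_bbb_negative: int = 40
    class_separation: float = 3.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_drugs", "attachment_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("approved_fraction", "missing_score_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < self.attachment_m + 1:
            raise ValueError("n_genes must exceed attachment_m")
        if self.n_planted_drugs > self.n_drugs:
            raise ValueError("n_planted_drugs exceeds n_drugs")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _drug_names(n: int) -> list[str]:
    return [f"DRUG{i:04d}" for i in range(n)]


def gen_drug_names(cfg: SyntheticConfig) -> list[str]:
    """Drug name universe with modality-revealing suffixes on the tail rows.

    The last ``biologic_fraction`` of names end in "-MAB" and the preceding
    ``peptide_fraction`` in "-TIDE", so nomenclature-based modality
    classification is exercised end to end with one consistent name list.
    """
    names = _drug_names(cfg.n_drugs)
    n_pep = int(round(cfg.peptide_fraction * cfg.n_drugs))
    n_bio = int(round(cfg.biologic_fraction * cfg.n_drugs))
    for i in range(n_bio):
        j = cfg.n_drugs - 1 - i
        names[j] = names[j] + "-MAB"
    for i in range(n_pep):
        j = cfg.n_drugs - 1 - n_bio - i
        names[j] = names[j] + "-TIDE"
    return names


def gen_ppi_network(cfg: SyntheticConfig) -> tuple[nx.Graph, list[str]]:
    """Scale-free gene interaction network with a planted disease module.

    Preferential attachment gives the degree distribution its power-law tail;
    the first ``n_target_genes`` genes are additionally wired into a dense
    module. When ``exact_edges`` is set, random edges are added or removed
    (module edges protected) until the count is exact, enabling fixtures with
    a prescribed density. Edge weights are confidence-like values in
    [0.4, 1.0].
    """
    rng = np.random.default_rng(cfg.seed)
    graph = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment_m, seed=cfg.seed)
    names = _gene_names(cfg.n_genes)
    graph = nx.relabel_nodes(graph, dict(enumerate(names)))
    module = names[: cfg.n_target_genes]
    module_edges = set()
    # densify the module: each module gene links ~half the other module genes
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            if rng.random() < 0.5:
                graph.add_edge(a, b)
                module_edges.add(frozenset((a, b)))
    if cfg.exact_edges is not None:
        while graph.number_of_edges() > cfg.exact_edges:
            candidates = [
                e for e in graph.edges() if frozenset(e) not in module_edges
            ]
            u, v = candidates[rng.integers(len(candidates))]
            graph.remove_edge(u, v)
        while graph.number_of_edges() < cfg.exact_edges:
            u, v = rng.choice(cfg.n_genes, size=2, replace=False)
            graph.add_edge(names[u], names[v])
    for _, _, attrs in graph.edges(data=True):
        attrs["weight"] = float(np.round(0.4 + 0.6 * rng.random(), 4))
    return graph, module


def gen_pathway_table(
    genes: list[str], module_genes: list[str], cfg: SyntheticConfig
) -> list[PathwayAnnotation]:
    """Per-gene Poisson pathway memberships across five database types.

    Module genes receive higher membership counts and smaller adjusted
    p-values (drawn log-uniform), emulating disease-module enrichment.
    Zero-pathway genes are possible for background genes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    module = set(module_genes)
    rows: list[PathwayAnnotation] = []
    for gene in genes:
        enriched = gene in module
        lam = 6.0 if enriched else 2.0
        n_records = rng.poisson(lam)
        for k in range(n_records):
            db = _DB_TYPES[rng.integers(len(_DB_TYPES))]
            lo, hi = (-10.0, -3.0) if enriched else (-6.0, np.log10(0.05))
            adj_p = 10 ** rng.uniform(lo, hi)
            rows.append(
                PathwayAnnotation(
                    gene=gene, pathway_id=f"PW_{gene}_{k}", db_type=db, adj_p=adj_p
                )
            )
    return rows


def gen_flags_table(
    genes: list[str], module_genes: list[str], cfg: SyntheticConfig
) -> list[GeneFeatureFlags]:
    """Structural/functional flags; module genes carry disease annotations."""
    rng = np.random.default_rng(cfg.seed + 2)
    module = set(module_genes)
    categories = list(TEMPORAL_WEIGHTS)
    rows = []
    for gene in genes:
        in_module = gene in module
        rows.append(
            GeneFeatureFlags(
                gene=gene,
                is_membrane=bool(rng.random() < (0.6 if in_module else 0.3)),
                is_enzyme=bool(rng.random() < 0.25),
                is_gpcr=bool(rng.random() < 0.1),
                is_ion_channel=bool(rng.random() < (0.3 if in_module else 0.08)),
                is_neurotransmitter=bool(rng.random() < (0.4 if in_module else 0.1)),
                is_known_ad_target=in_module,
                ad_pathway_overlap=int(rng.integers(5, 15)) if in_module else int(rng.integers(0, 4)),
                temporal_category=categories[rng.integers(len(categories))]
                if in_module
                else "uncategorized",
            )
        )
    return rows


def gen_interactions(
    drugs: list[str], genes: list[str], module_genes: list[str], cfg: SyntheticConfig
) -> list[InteractionRecord]:
    """Sparse bipartite drug-gene interactions with planted true positives.

    The first ``n_planted_drugs`` drugs receive several high-score edges into
    the disease module (guaranteed at least one); decoy drugs wire uniformly
    at random over all genes. A configurable fraction of records is emitted
    without a score, exercising the 0.5 imputation downstream.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    planted = drugs[: cfg.n_planted_drugs]
    rows: list[InteractionRecord] = []

    def _maybe_score(score: float) -> float | None:
        return None if rng.random() < cfg.missing_score_fraction else float(np.round(score, 3))

    for drug in planted:
        n_edges = max(1, int(rng.integers(3, max(4, len(module_genes) // 2 + 1))))
        chosen = rng.choice(len(module_genes), size=min(n_edges, len(module_genes)), replace=False)
        for gi in chosen:
            rows.append(
                InteractionRecord(
                    drug=drug,
                    gene=module_genes[int(gi)],
                    score=_maybe_score(0.7 + 0.3 * rng.random()),
                )
            )
    for drug in drugs[cfg.n_planted_drugs :]:
        n_edges = int(rng.integers(1, 5))
        chosen = rng.choice(len(genes), size=n_edges, replace=False)
        for gi in chosen:
            rows.append(
                InteractionRecord(
                    drug=drug,
                    gene=genes[int(gi)],
                    score=_maybe_score(rng.random()),
                )
            )
    return rows


def gen_drug_records(drugs: list[str], cfg: SyntheticConfig) -> list[DrugRecord]:
    """Approval flags drawn at the configured approved fraction."""
    rng = np.random.default_rng(cfg.seed + 4)
    return [
        DrugRecord(name=d, approved=bool(rng.random() < cfg.approved_fraction))
        for d in drugs
    ]


def _truncated_normal(rng, mean, sd, lower, upper, size):
    """Rejection-free truncation by resampling out-of-bound draws."""
    x = rng.normal(mean, sd, size)
    bad = (x < lower) | (x > upper)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lower) | (x > upper)
    return x


def gen_property_table(drugs: list[str], cfg: SyntheticConfig) -> pd.DataFrame:
    """Physicochemical descriptor table with modality-scale minorities.

    Most rows are small-molecule-scale draws from truncated normals at the
    configured means/SDs (MW > 50 Da, PSA >= 0, counts >= 0); drugs whose
    names carry a "-TIDE" suffix are emitted at peptide scale (MW 450-1500
    Da) and "-MAB" names at biologic scale (MW > 1500 Da), matching the
    nomenclature-based modality classifier.
    """
    rng = np.random.default_rng(cfg.seed + 5)
    n = len(drugs)
    m = cfg.property_means
    s = cfg.property_sds
    mw = _truncated_normal(rng, m["mw"], s["mw"], 50.0, 2000.0, n)
    logp = rng.normal(m["logp"], s["logp"], n)
    psa = _truncated_normal(rng, m["psa"], s["psa"], 0.0, 500.0, n)
    hbd = np.clip(np.round(rng.normal(m["hbd"], s["hbd"], n)), 0, None).astype(int)
    hba = np.clip(np.round(rng.normal(m["hba"], s["hba"], n)), 0, None).astype(int)
    rot = np.clip(np.round(rng.normal(4.0, 2.0, n)), 0, None).astype(int)

    for j, name in enumerate(drugs):
        upper = name.upper()
        if upper.endswith("-TIDE"):
            mw[j] = rng.uniform(500.0, 1400.0)
            logp[j] = rng.uniform(-2.0, 1.0)
            psa[j] = rng.uniform(150.0, 400.0)
            hbd[j] = rng.integers(5, 15)
            hba[j] = rng.integers(8, 20)
        elif upper.endswith("-MAB"):
            mw[j] = rng.uniform(2000.0, 150000.0)
            logp[j] = rng.uniform(-8.0, -2.0)
            psa[j] = rng.uniform(500.0, 2000.0)
            hbd[j] = rng.integers(20, 80)
            hba[j] = rng.integers(30, 120)
    return pd.DataFrame(
        {
            "drug": list(drugs),
            "mw": np.round(mw, 2),
            "logp": np.round(logp, 2),
            "psa": np.round(psa, 2),
            "hbd": hbd,
            "hba": hba,
            "rotatable_bonds": rot,
        }
    )


def gen_bbb_validation(cfg: SyntheticConfig) -> pd.DataFrame:
    """Two-class labeled descriptor set for supervised barrier validation.

    Penetrant compounds cluster at CNS-favorable descriptor values; the
    non-penetrant class is shifted by ``class_separation`` standardized units
    in the unfavorable direction per descriptor (heavier, less lipophilic,
    more polar). Default sizes are 70 penetrant / 40 non-penetrant.
    """
    if cfg.class_separation < 0:
        raise ValueError("class_separation must be nonnegative")
    rng = np.random.default_rng(cfg.seed + 6)
    base_mean = np.array([300.0, 2.5, 50.0, 1.0, 3.0])
    base_sd = np.array([60.0, 0.8, 15.0, 0.8, 1.5])
    shift_dir = np.array([1.0, -1.0, 1.0, 1.0, 1.0])  # unfavorable direction
    pos = rng.normal(base_mean, base_sd, size=(cfg.n_bbb_positive, 5))
    neg_mean = base_mean + shift_dir * cfg.class_separation * base_sd
    neg = rng.normal(neg_mean, base_sd, size=(cfg.n_bbb_negative, 5))
    x = np.vstack([pos, neg])
    x[:, 0] = np.clip(x[:, 0], 50.0, None)
    x[:, 2] = np.clip(x[:, 2], 0.0, None)
    x[:, 3] = np.clip(np.round(x[:, 3]), 0, None)
    x[:, 4] = np.clip(np.round(x[:, 4]), 0, None)
    labels = np.concatenate(
        [np.ones(cfg.n_bbb_positive, dtype=int), np.zeros(cfg.n_bbb_negative, dtype=int)]
    )
    names = [f"CPD{i:03d}" for i in range(len(labels))]
    return pd.DataFrame(
        {
            "drug": names,
            "mw": np.round(x[:, 0], 2),
            "logp": np.round(x[:, 1], 2),
            "psa": np.round(x[:, 2], 2),
            "hbd": x[:, 3].astype(int),
            "hba": x[:, 4].astype(int),
            "cns_label": labels,
        }
    )
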