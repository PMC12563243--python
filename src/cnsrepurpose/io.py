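"""Readers and writers for the tabular interchange formats.

All inputs are plain TSV/CSV; readers return the package's domain objects or
pandas DataFrames and validate the minimum schema, writers produce files that
round-trip losslessly through the corresponding reader.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .mnptd import GeneFeatureFlags, PathwayAnnotation
from .netmed import DrugRecord, InteractionRecord

__all__ = [
    "read_network_tsv",
    "write_network_tsv",
    "read_pathway_tsv",
    "read_flags_tsv",
    "read_interactions_tsv",
    "read_properties_table",
    "read_bbb_table",
    "write_table",
    "read_candidate_table",
]

_FLAG_COLUMNS = [
    "is_membrane",
    "is_enzyme",
    "is_gpcr",
    "is_ion_channel",
    "is_neurotransmitter",
    "is_known_ad_target",
]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_network_tsv(path: str | Path) -> nx.Graph:
    """Undirected weighted edge list: gene_a <TAB> gene_b <TAB> weight."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["gene_a", "gene_b"], path)
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        weight = float(getattr(row, "weight", 1.0))
        graph.add_edge(str(row.gene_a), str(row.gene_b), weight=weight)
    return graph


def write_network_tsv(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"gene_a": u, "gene_b": v, "weight": attrs.get("weight", 1.0)}
        for u, v, attrs in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_pathway_tsv(path: str | Path) -> list[PathwayAnnotation]:
    """Columns: gene, pathway_id, db_type, adj_p."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["gene", "pathway_id", "db_type", "adj_p"], path)
    return [
        PathwayAnnotation(
            gene=str(r.gene),
            pathway_id=str(r.pathway_id),
            db_type=str(r.db_type),
            adj_p=float(r.adj_p),
        )
        for r in df.itertuples(index=False)
    ]


def read_flags_tsv(path: str | Path) -> list[GeneFeatureFlags]:
    """Gene annotation flags; booleans encoded as 0/1 columns."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["gene"], path)
    flags = []
    for r in df.itertuples(index=False):
        kwargs = {c: bool(getattr(r, c)) for c in _FLAG_COLUMNS if hasattr(r, c)}
        if hasattr(r, "base_druggability") and pd.notna(r.base_druggability):
            kwargs["base_druggability"] = float(r.base_druggability)
        if hasattr(r, "direct_ad_association") and pd.notna(r.direct_ad_association):
            kwargs["direct_ad_association"] = float(r.direct_ad_association)
        if hasattr(r, "ad_pathway_overlap"):
            kwargs["ad_pathway_overlap"] = int(r.ad_pathway_overlap)
        if hasattr(r, "temporal_category"):
            kwargs["temporal_category"] = str(r.temporal_category)
        flags.append(GeneFeatureFlags(gene=str(r.gene), **kwargs))
    return flags


def read_interactions_tsv(
    path: str | Path,
) -> tuple[list[DrugRecord], list[InteractionRecord]]:
    """Drug-gene interaction table: drug_name, approved, gene_symbol[, interaction_score].

    Rows with an empty score are kept with ``score=None`` (imputed to 0.5 at
    network construction). Returns deduplicated drug records and all
    interaction records.
    """
    df = pd.read_csv(path, sep="\t")
    _require(df, ["drug_name", "approved", "gene_symbol"], path)
    has_score = "interaction_score" in df.columns
    drugs: dict[str, DrugRecord] = {}
    interactions = []
    for r in df.itertuples(index=False):
        rec = DrugRecord(name=str(r.drug_name), approved=bool(r.approved))
        drugs.setdefault(rec.name, rec)
        score = None
        if has_score and pd.notna(r.interaction_score):
            score = float(r.interaction_score)
        interactions.append(
            InteractionRecord(drug=str(r.drug_name), gene=str(r.gene_symbol), score=score)
        )
    return list(drugs.values()), interactions


def read_properties_table(path: str | Path) -> pd.DataFrame:
    """Physicochemical property table (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    _require(df, ["drug", "mw", "logp", "psa", "hbd", "hba"], path)
    return df


def read_bbb_table(path: str | Path) -> pd.DataFrame:
    """Labeled barrier-penetration table: five descriptors plus cns_label."""
    df = read_properties_table(path)
    _require(df, ["cns_label"], path)
    if not set(df["cns_label"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: cns_label must be binary 0/1")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV writer used for all score/assessment outputs."""
    df.to_csv(path, sep="\t", index=False)


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read back a ranked candidate table, with line-numbered parse errors."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed candidate table: {exc}") from exc
    _require(df, ["drug", "modality", "medchem_score", "rank_in_modality"], path)
    return df
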