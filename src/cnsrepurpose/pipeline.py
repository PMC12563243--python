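"""End-to-end orchestration: filter -> networks -> scores -> assessment -> ranking.

Composes the CNS pre-filter, multi-layer network construction, restart-walk
scoring, supervised barrier-penetration prediction, and medicinal-chemistry
assessment into one deterministic run producing a modality-ranked candidate
table and a run manifest. Inputs come either from files or from the seeded
synthetic generators.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bbbml, io, medchem, netmed, synthdata
from .medchem import CandidateAnnotation, PhyschemProfile
from .netmed import CNSFilterConfig, RWRConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """One document of every tunable constant, with the printed defaults.

    When the input paths are None the seeded synthetic generators supply the
    corresponding table, so the pipeline runs end to end without downloads.
    """

    seed: int = 42
    interactions_path: str | None = None
    properties_path: str | None = None
    bbb_labels_path: str | None = None
    targets: list[str] = field(default_factory=list)
    out_dir: str = "results"
    rwr: RWRConfig = field(default_factory=RWRConfig)
    cns_filter: CNSFilterConfig = field(default_factory=CNSFilterConfig)
    combined_weights: tuple[float, float, float] = netmed.COMBINED_WEIGHTS
    sim_threshold: float = 0.15
    evidence_table: dict = field(default_factory=dict)
    synth: synthdata.SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.combined_weights) - 1.0) > 1e-9:
            raise ValueError("combined score weights must sum to 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "rwr" in kwargs:
        kwargs["rwr"] = RWRConfig(**kwargs["rwr"])
    if "cns_filter" in kwargs:
        kwargs["cns_filter"] = CNSFilterConfig(**kwargs["cns_filter"])
    if "synth" in kwargs and kwargs["synth"] is not None:
        kwargs["synth"] = synthdata.SyntheticConfig(**kwargs["synth"])
    if "combined_weights" in kwargs:
        kwargs["combined_weights"] = tuple(kwargs["combined_weights"])
    return PipelineConfig(**kwargs)


def _log_stage(stage: str, count: int) -> None:
    logger.info("stage=%s rows=%d", stage, count)
    print(f"[pipeline] {stage}: {count}", file=sys.stderr)


def run_pipeline(cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Run every stage in order and return the ranked table plus a manifest.

    Stages: load/generate inputs, CNS filter, layer construction, network
    scoring against the target genes, supervised BBB training and prediction,
    medicinal-chemistry assessment, and modality-stratified ranking. Row
    counts per stage are logged to stderr; identical config and seed give
    identical outputs.
    """
    synth_cfg = cfg.synth or synthdata.SyntheticConfig(seed=cfg.seed)

    # --- inputs -----------------------------------------------------------
    if cfg.interactions_path:
        drugs, interactions = io.read_interactions_tsv(cfg.interactions_path)
    else:
        names = synthdata.gen_drug_names(synth_cfg)
        genes = [f"G{i:04d}" for i in range(synth_cfg.n_genes)]
        _, module = synthdata.gen_ppi_network(synth_cfg)
        drugs = synthdata.gen_drug_records(names, synth_cfg)
        interactions = synthdata.gen_interactions(names, genes, module, synth_cfg)
    targets = list(cfg.targets)
    if not targets:
        _, module = synthdata.gen_ppi_network(synth_cfg)
        targets = module
    if cfg.properties_path:
        properties = io.read_properties_table(cfg.properties_path)
    else:
        properties = synthdata.gen_property_table([d.name for d in drugs], synth_cfg)
    if cfg.bbb_labels_path:
        bbb_labels = io.read_bbb_table(cfg.bbb_labels_path)
    else:
        bbb_labels = synthdata.gen_bbb_validation(synth_cfg)
    _log_stage("drugs_in", len(drugs))

    # --- CNS pre-filter ---------------------------------------------------
    retained = netmed.cns_filter(drugs, interactions, cfg.cns_filter)
    if retained.empty:
        raise RuntimeError("0 drugs retained by the CNS filter")
    kept = set(retained["drug"])
    interactions = [r for r in interactions if r.drug in kept]
    _log_stage("after_filter", len(kept))

    # --- networks and scores ----------------------------------------------
    genes = sorted({r.gene for r in interactions} | set(targets))
    layers = netmed.build_layers(
        sorted(kept), genes, interactions, sim_threshold=cfg.sim_threshold
    )
    scores = netmed.score_drugs(layers, sorted(kept), targets, interactions, cfg.rwr)
    scores["combined"] = (
        cfg.combined_weights[0] * scores["rwr"]
        + cfg.combined_weights[1] * scores["proximity"]
        + cfg.combined_weights[2] * scores["direct"]
    )
    _log_stage("scored", len(scores))

    # --- supervised BBB model ---------------------------------------------
    validation = bbbml.run_validation(bbb_labels, seed=cfg.seed)
    best = validation["models"][validation["best_model"]]
    candidate_props = properties[properties["drug"].str.upper().isin(kept)]
    preds = bbbml.predict_bbb(best, validation["params"], candidate_props)
    ml_probs = dict(zip(preds["drug"].str.upper(), preds["probability"]))
    _log_stage("bbb_predicted", len(preds))

    # --- medicinal chemistry assessment and ranking ------------------------
    approved = {d.name: d.approved for d in drugs}
    profiles = [
        PhyschemProfile(
            drug=str(r.drug),
            mw=float(r.mw),
            logp=float(r.logp),
            psa=float(r.psa),
            hbd=int(r.hbd),
            hba=int(r.hba),
            rotatable_bonds=int(r.rotatable_bonds) if hasattr(r, "rotatable_bonds") else None,
        )
        for r in candidate_props.itertuples(index=False)
    ]
    annotations = {
        p.drug.upper(): CandidateAnnotation(
            drug=p.drug.upper(), approved=approved.get(p.drug.upper(), False)
        )
        for p in profiles
    }
    table = medchem.assess_candidates(
        profiles,
        scores,
        annotations=annotations,
        ml_probabilities=ml_probs,
        evidence_table=cfg.evidence_table,
    )
    _log_stage("assessed", len(table))

    manifest = {
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "best_bbb_model": validation["best_model"],
        "filter_retention_pct": netmed.retention_percentage(len(kept), len(drugs)),
        "stage_counts": {
            "drugs_in": len(drugs),
            "after_filter": len(kept),
            "scored": len(scores),
            "assessed": len(table),
        },
    }
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_table(table, out_dir / "candidates.tsv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return table, manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    return d
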