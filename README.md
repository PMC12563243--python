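# cnsrepurpose

Network-medicine drug repurposing for central-nervous-system (CNS) disease,
with explicit blood–brain-barrier (BBB) modeling.

## The problem

Most computational drug-repurposing pipelines rank candidates purely by
network proximity between a drug's targets and a disease gene module. For CNS
indications this is not enough: a drug that cannot cross the blood–brain
barrier is useless regardless of how well its targets overlap the disease
module, and development feasibility differs sharply between small molecules,
peptides, and biologics. This package integrates four stages into one
reproducible pipeline:

1. **Gene prioritization** (`cnsrepurpose.mnptd`) — ranks genes on a
   protein-interaction network by combining four dimensions: *network
   plasticity* (how much removing the gene would perturb the network, built
   from degree, betweenness, closeness, and eigenvector centrality),
   *pathway centrality* (diversity, significance, and count of enrichment
   records across five annotation databases), *druggability* (structural
   class bonuses for membrane proteins, enzymes, GPCRs, ion channels, and
   neurotransmitter receptors), and *disease proximity* (direct association,
   centrality, and pathway overlap with the disease module). The four
   dimensions are combined with adaptive weights and scaled by a temporal
   intervention-stage weight. Significance is assessed by label permutation
   against per-gene null distributions, stability by bootstrap resampling.
2. **Network scoring** (`cnsrepurpose.netmed`) — builds a multi-layer
   pharmacogenomic network (bipartite drug–gene interactions plus
   Jaccard-similarity drug–drug and gene–gene layers, threshold 0.15) and
   scores each drug against the target-gene set by random walk with restart
   (restart probability 0.7), shortest-path proximity, and direct-interaction
   evidence, combined 0.4/0.3/0.3. A multi-criteria CNS pre-filter restricts
   the drug universe first.
3. **Medicinal-chemistry assessment** (`cnsrepurpose.medchem`) — a
   six-criterion weighted BBB rule score (max 6.0), supervised-probability
   class bands, P-glycoprotein efflux liability, structural-alert reactivity,
   four-class tractability with feasibility/timeline mapping, therapeutic
   modality classification, and a BBB/reactivity penalty applied to the
   network score with modality-specific multipliers.
4. **Supervised BBB validation** (`cnsrepurpose.bbbml`) — trains four
   classifier families (random forest, gradient boosting, XGBoost, RBF SVM
   with Platt calibration) on five physicochemical descriptors, selects the
   best by balanced accuracy on a stratified held-out split, and produces
   calibrated penetration probabilities for the candidates.

Because the original interaction databases are not redistributable, the
package ships seeded synthetic generators (`cnsrepurpose.synthdata`) that
emulate the statistical shape of each input — a scale-free interaction
network with a planted disease module, enriched pathway annotations, a sparse
drug–gene interaction table with planted true positives, CNS-like property
distributions, and a separable two-class BBB validation set. Every generator
is a pure function of its seed.

## The core model

For gene *i* with centralities DC (degree), BC (betweenness), CC (closeness),
EC (eigenvector) and raw degree *k*:

```
plasticity  P_i = (DC·BC + k·(1−CC) + EC·DC·BC) / 3
PCI_i       = 0.3·diversity + 0.4·mean(−log10 p) + 0.1·count + 0.2·weighted mean(−log10 p)
druggability D_i = min(1, base + class bonuses)
proximity   DP_i = 0.4·association + 0.3·centrality + 0.2·pathway + 0.1·functional
score       FS_i = temporal_weight · Σ_d w_d · score_d    (w adaptively reweighted, Σw = 1)
```

For drug *j* against target set *T* on the integrated network:

```
RWR:       p ← (1−α)·P·p + α·p0,  α = 0.7, seeded uniformly on T
proximity: S_NP = 1 / (1 + mean shortest-path distance to T)
combined:  S = 0.4·S_RWR + 0.3·S_NP + 0.3·S_direct
adjusted:  S' = S · (1 − m·(0.3·(1−P_BBB) + 0.2·R))   m = 1 / 0.5 / 0.2 by modality
```

## Worked example

```python
from cnsrepurpose import medchem, pipeline, synthdata

profile = medchem.PhyschemProfile(
    drug="MEMANTINE", mw=179.3, logp=3.28, psa=26.0, hbd=1, hba=1, n_plus_o=1
)
bbb = medchem.bbb_rule_score(profile)
print(f"{profile.drug}: rule score {bbb.rule_score} -> class {bbb.rule_class}, "
      f"CNS compliant: {bbb.cns_compliant}")

cfg = pipeline.PipelineConfig(
    seed=42,
    out_dir="results",
    synth=synthdata.SyntheticConfig(seed=42, n_genes=200, n_drugs=100, n_target_genes=10),
)
table, manifest = pipeline.run_pipeline(cfg)
cols = ["drug", "modality", "network_score", "medchem_score", "bbb_ml_class",
        "tractability", "timeline", "rank_in_modality"]
print(table[cols].head(8).to_string(index=False))
print("best BBB model:", manifest["best_bbb_model"])
print("stage counts:", manifest["stage_counts"])
```

Output:

```
MEMANTINE: rule score 6.0 -> class High, CNS compliant: True
         drug       modality  network_score  medchem_score bbb_ml_class tractability  timeline  rank_in_modality
 DRUG0099-MAB       biologic       0.019839       0.018569      VeryLow           IV  Research                 1
DRUG0097-TIDE        peptide       0.024532       0.020607      VeryLow           IV  Research                 1
     DRUG0001 small_molecule       0.098797       0.096821         High            I Immediate                 1
     DRUG0002 small_molecule       0.097004       0.095064         High            I Immediate                 2
     DRUG0037 small_molecule       0.020686       0.020211         High            I Immediate                 3
     DRUG0068 small_molecule       0.020083       0.018898         High            I Immediate                 4
     DRUG0054 small_molecule       0.018967       0.018588         High            I Immediate                 5
     DRUG0005 small_molecule       0.013204       0.012365         High            I Immediate                 6
best BBB model: random_forest
stage counts: {'drugs_in': 100, 'after_filter': 53, 'scored': 53, 'assessed': 53}
```

The two planted drugs retained by the CNS filter (`DRUG0001`, `DRUG0002`)
surface at the top of the small-molecule ranking, and suffix-named compounds
are routed to their own modality rankings.

The same pipeline is available from the command line:

```bash
cnsrepurpose synth all --seed 42 --outdir data      # generate every input table
cnsrepurpose run --config pipeline.yaml             # run the full pipeline
cnsrepurpose mnptd --network data/network.tsv \
    --pathways data/pathways.tsv --flags data/flags.tsv -o genes.tsv
cnsrepurpose bbbml train --data data/bbb_labels.csv -o model/
```

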