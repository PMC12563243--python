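# Methods

This note documents the model implemented by `cnsrepurpose`, its assumptions,
every tunable parameter with units and defaults, what the synthetic data
generators do and do not emulate, the numerical choices, and the known
limitations.

## 1. Gene prioritization (`mnptd`)

### Model

Each gene on an undirected protein-interaction network is scored on four
dimensions, adaptively weighted, and scaled by a temporal intervention-stage
weight.

**Centralities.** Degree centrality DC = deg/(n−1); betweenness BC with the
standard 2/((n−1)(n−2)) normalization; closeness CC with Wasserman–Faust
component scaling (well-defined on disconnected graphs); eigenvector
centrality EC by power iteration on the largest connected component with unit
Euclidean norm, zero on other components (a lone largest component of one
node carries EC = 1). Self-loops are rejected.

**Plasticity.** P = (D + C + N)/3 with degree impact D = DC·BC, clustering
disruption C = k·(1−CC) using the *raw* degree k, and network influence
N = EC·D. Using the raw degree is deliberate: it lets hub plasticity reach
magnitudes of ~10 on realistic networks, so plasticity is not confined to
[0, 1].

**Pathway Centrality Index.** Over a gene's enrichment records
PCI = 0.3·diversity + 0.4·significance + 0.1·connectivity + 0.2·weighted
significance, where diversity is the count of distinct database types,
significance the mean −log10 adjusted p, connectivity the record count, and
weighted significance the database-weighted mean −log10 p with weights
GO_BP 1.0, KEGG 0.8, Reactome 0.6, GO_MF 0.4, Hallmark 0.3. Unannotated
genes score 0.

**Druggability.** base + 0.2·membrane + 0.15·enzyme + 0.3·GPCR +
0.25·ion-channel + 0.2·neurotransmitter, capped at 1. Default base: 0.3 for
known disease targets, 0.1 otherwise.

**Disease proximity.** DP = 0.4·DA + 0.3·CP + 0.2·PP + 0.1·FP with direct
association DA (default 1 for known disease genes, 0 otherwise), centrality
proximity CP = (DC + BC + EC)/3, pathway proximity PP = min(1, overlap/10),
and functional proximity FP = 0.8·PP (a fixed proxy for GO-term overlap).

**Adaptive integration.** Weights start at 0.25 each; the plasticity weight
is multiplied by 1.3 when plasticity > 0.5, the pathway weight by 1.2 when
PCI > 1.0, the druggability weight by 1.5 for membrane proteins; weights are
renormalized to sum to 1 before the weighted sum. Final score
FS = IS·TW with temporal weights early_intervention 1.0, neuroprotection 0.9,
progression_modifier 0.8, symptomatic 0.6, uncategorized 0.5.

### Inference

**Permutation test.** The null reassigns whole dimensional-score vectors to
gene labels (n_perm default 1000, minimum 100, seed default 42) and
recomputes the integrated, temporally weighted score with each gene's own
membrane flag and temporal weight. A gene is significant when its observed
score strictly exceeds the 95th percentile of its own null; reported
p-values use the add-one correction (r+1)/(n+1). Under exchangeable scores
the test fires at the nominal 5% rate (verified in the test suite).

**Bootstrap stability.** Genes are resampled with replacement (n_boot 1000);
the coefficient of variation of a gene's score is computed over replicates in
which it appears (exactly zero for deterministic inputs), and top-k
membership frequency is conditional on the gene being sampled, so a dominant
gene attains frequency 1.0.

## 2. Multi-layer network scoring (`netmed`)

**CNS pre-filter.** A drug is retained if it passes any of: case-insensitive
name-keyword match (default keywords: neuro, brain, cognitive, psychiatric,
anticonvulsant, analgesic, antipsychotic), curated-list membership,
interaction with a gene matching a neuro-gene keyword (GABR, GRIN, GRIA, DRD,
HTR, CHRN, CHRM, APP, PSEN, APOE, SNCA, LRRK2, MAOA, COMT, SLC6A3, SLC6A4),
or regulatory approval (on by default). Provenance columns record which
criteria fired.

**Layers.** The bipartite drug–gene layer carries interaction confidence
scores (missing scores imputed to 0.5). Drug–drug and gene–gene layers
connect pairs whose Jaccard similarity over shared targets (shared binders)
is ≥ 0.15 (inclusive). The integrated graph is the union of the three layers.
Drug and gene nodes are namespaced tuples to prevent name collisions.

**Random walk with restart.** p ← (1−α)·P·p + α·p0 with column-normalized
weighted adjacency P, restart probability α = 0.7, uniform restart vector
over the seed (target) genes, L1 convergence tolerance 1e−6, max 1000
iterations. Degree-zero (dangling) columns teleport their mass back to the
restart distribution, so the stationary vector is a probability distribution
(mass conservation is asserted in tests, and the iterate is checked against a
direct linear solve of (I − (1−α)P)p = αp0 to 1e−6). Graphs above the node
budget (default 10,000) are reduced to a breadth-first neighborhood around
the targets with lexicographic ordering inside each hop shell.

**Proximity and direct evidence.** S_NP = 1/(1 + d̄) with d̄ the mean
shortest-path distance from the drug to the targets; unreachable pairs are
penalized with a finite distance equal to the node count. Direct evidence is
the mean interaction weight over targets (zero where no edge exists).

**Combined score.** S = 0.4·S_RWR + 0.3·S_NP + 0.3·S_direct. A diffusion
proximity (restart 0.5, seeded at the targets, read at the drug) is reported
as a side output and does not enter the combined score. Effective resistance
distance is available for graphs of ≤ 2000 nodes (dense pseudoinverse).

## 3. Medicinal-chemistry assessment (`medchem`)

**BBB rule score** (max 6.0): MW ≤ 450 Da earns 1.0; 1.5 ≤ LogP ≤ 3.5 earns
2.0; PSA ≤ 70 Å² earns 1.0; HBD ≤ 3 earns 0.5; HBA ≤ 7 earns 0.5; N+O atom
count ≤ 5 earns 1.0 (HBA stands in when the atom count is missing, flagged as
approximated). Rule classes: ≥5 High, [4,5) ModerateHigh, [3,4) Moderate,
[2,3) Low, <2 VeryLow. Supervised probability bands use the same labels at
0.8/0.6/0.4/0.2 (lower edges inclusive).

**P-gp liability.** Risk factors MW > 400 Da, LogP > 3.0, HBA ≥ 8; zero
factors Low, one Moderate, two or more High.

**Reactivity.** Maximum risk over matched structural alerts (default table:
acyl halide VeryHigh; protein crosslinker, Michael acceptor, epoxide High;
electrophile, nitroaromatic, quinone, aldehyde Moderate); numeric scores
Low 0.1, Moderate 0.4, High 0.7, VeryHigh 1.0. Unknown flags warn and are
ignored.

**Tractability.** Three criteria: favorable BBB class (High/ModerateHigh),
acceptable reactivity (Low/Moderate), MW ≤ 450 Da. All three → Class I,
exactly two → Class II, otherwise Class IV when the BBB class is VeryLow,
else Class III. Feasibility maps I→High, II→ModerateHigh, III→Moderate,
IV→Low; timeline is Immediate for approved Class I, ShortTerm for
experimental Class I, MediumTerm/LongTerm for II/III, Research for IV.
Safety: High/VeryHigh reactivity → HighRisk; Low reactivity plus full CNS
compliance → SafeForCNS; otherwise LowRisk. When a supervised probability is
available its class drives tractability; otherwise the rule class does.

**Modality.** Precedence: curated known peptides; biologic nomenclature
suffixes (-MAB, -ZUMAB, -CEPT, -TINIB) or MW > 1500 Da; the 450–1500 Da
window with peptidic evidence (suffix -TIDE/-PRESSIN or an annotation flag);
otherwise small molecule.

**Penalty and adjustment.** penalty = 0.3·(1−P_BBB) + 0.2·R ∈ [0, 0.5]
(neutral prior P_BBB = 0.5 when no supervised probability exists); adjusted
score = combined·(1 − m·penalty) with modality multipliers small molecule
1.0, peptide 0.5, biologic 0.2 — peptides and biologics are penalized less
because transporter-mediated delivery and receptor-mediated transcytosis
partly bypass passive-diffusion criteria. Candidates are ranked within each
modality by adjusted score, ties broken by supervised probability (small
molecules, peptides) or direct-interaction score (biologics), then name.

Known inconsistencies in the published characterization rows this rule set
was checked against are kept as *documented exceptions* in the test suite
(one tractability cell that contradicts its own molecular weight, one
penetration-class cell that contradicts the probability bands, and six
P-gp cells that contradict the factor rule); the rules as stated are
implemented, not the discrepant cells.

## 4. Supervised BBB validation (`bbbml`)

Features: MW (Da), LogP, PSA (Å²), HBD, HBA. The split is stratified and
deterministic: per class, round(class_n·test_frac) rows go to the test set
(default test_frac 0.2, seed 42; a 70/40 set yields 56/32 train and 14/8
test). Features are z-scored with training-set mean and *population*
(divide-by-n) standard deviation; constant training features are rejected;
test data are transformed with training parameters only (no leakage).

Families: random forest (200 trees, depth 10), gradient boosting (100
estimators, depth 5, learning rate 0.1), XGBoost (same, lazy import,
optional), RBF SVM (C = 1, gamma scale) wrapped in sigmoid (Platt)
calibration. AUC-ROC is computed by the Mann–Whitney rank statistic with
mid-ranks for ties (cross-checked against scikit-learn in tests). Metrics
with empty denominators are reported as None with a warning. The deployed
model maximizes balanced accuracy, ties broken by AUC, then a fixed family
order. Binary calls threshold probabilities at 0.5 (inclusive).

## 5. Synthetic data (`synthdata`)

Every generator is a pure function of a `SyntheticConfig`; sub-generators use
fixed seed offsets so tables can be regenerated independently.

| Parameter | Default | Meaning |
|---|---|---|
| seed | 42 | master seed |
| n_genes / n_drugs | 500 / 300 | universe sizes |
| attachment_m | 2 | preferential-attachment edges per new node |
| n_target_genes | 20 | planted disease-module size |
| n_planted_drugs | 5 | true-positive drugs wired into the module |
| approved_fraction | 0.5 | fraction of approved drugs |
| missing_score_fraction | 0.1 | interaction rows emitted without a score |
| exact_edges | None | optional exact edge count for density fixtures |
| peptide_fraction / biologic_fraction | 0.02 / 0.01 | tail names suffixed -TIDE / -MAB |
| property means (MW, LogP, PSA, HBD, HBA) | 317.8 Da, 2.18, 52.3 Å², 1.4, 3.2 | small-molecule truncated normals |
| property SDs | 77.4, 0.96, 20.2, 1.1, 2.0 | idem |
| n_bbb_positive / n_bbb_negative | 70 / 40 | labeled validation set sizes |
| class_separation | 3.0 | shift between classes in per-feature SD units |

The network is Barabási–Albert preferential attachment with the disease
module additionally densified (each module pair wired with probability 0.5);
module genes get more pathway records (Poisson λ 6 vs 2) with smaller
adjusted p-values, disease annotations, and temporal categories. Planted
drugs receive several high-confidence (≥ 0.7) edges into the module; decoys
wire uniformly at random. The BBB set draws penetrant compounds around
CNS-favorable descriptor values (MW 300 ± 60, LogP 2.5 ± 0.8, PSA 50 ± 15,
HBD 1 ± 0.8, HBA 3 ± 1.5) and shifts the non-penetrant class by
class_separation standardized units in the unfavorable direction.

**What the synthetic data does and does not emulate.** It reproduces the
*statistical shape* the method assumes: power-law degree distribution, a
dense disease module, enrichment contrast, interaction sparsity and
missingness, realistic descriptor ranges, and class separation. It does not
emulate real biology: gene identities, literature-derived interaction
confidences, correlated descriptor structure of real chemotypes, or the
hardness of real BBB prediction. Passing the planted-recovery and synthetic
BBB tests therefore demonstrates that the machinery is correct and sensitive
under its own assumptions — not that it would achieve comparable accuracy on
experimental data.

## 6. Pipeline and numerical choices

`pipeline.run_pipeline` composes filter → layers → scores → supervised BBB →
assessment → modality ranking; inputs come from files or from the generators;
outputs are a ranked TSV, and a JSON manifest with the seed, a SHA-256 config
hash, the selected model, the filter retention percentage, and per-stage row
counts (also logged to stderr). Identical configuration and seed give
identical outputs.

Numerical choices: sparse column-normalized transition matrices (CSC) for the
walk; L1 convergence; dangling-node teleportation for mass conservation;
population-SD standardization so tiny training sets scale exactly; rank-based
AUC (exact, no trapezoid binning); mergesort (stable) for every ranking with
explicit lexicographic tie-breaks, making all orderings deterministic.

Problem sizes are desk-scale by choice: a few hundred genes and drugs, which
every test covers in seconds on one CPU. The algorithms themselves accept
larger inputs (walk subsampling above 10,000 nodes; resistance distance
guarded at 2000 nodes).

## 7. Open design decisions and limitations

- The plasticity disruption term intentionally uses raw degree, so plasticity
  is unbounded above; the adaptive integration does not rescale dimensions to
  a common range, so plasticity can dominate for extreme hubs.
- Functional proximity is a fixed 0.8 proxy of pathway proximity rather than
  a real GO-overlap computation.
- The permutation null permutes score vectors jointly, preserving per-gene
  flag/weight structure but not network dependence between dimensions.
- The CNS filter's approval criterion deliberately over-retains (any approved
  drug passes); retention percentages are only comparable under the same
  filter configuration.
- Rule-based BBB scoring ignores active transport, efflux kinetics, and
  plasma protein binding; P-gp liability is a three-factor heuristic, not a
  transporter assay model.
- The supervised validator sees five bulk descriptors only; on real data its
  accuracy ceiling is well below what the separable synthetic set suggests.
- Biologic candidates are scored by the same network machinery but their BBB
  treatment (0.2 penalty multiplier) is a placeholder for explicit
  transcytosis modeling.
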