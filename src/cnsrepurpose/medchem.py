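"""Medicinal-chemistry assessment of CNS drug-repurposing candidates.

Rule-based blood-brain-barrier scoring over six physicochemical criteria,
CNS drug-likeness compliance, P-glycoprotein efflux liability, chemical
reactivity and safety stratification, four-class tractability with
feasibility/timeline mapping, therapeutic-modality classification, the
BBB/reactivity penalty applied to network scores with modality-specific
multipliers, evidence-level annotation, and modality-stratified ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "PhyschemProfile",
    "BBBAssessment",
    "TractabilityAssessment",
    "ModalityAdjustedScore",
    "CandidateAnnotation",
    "BBB_CRITERIA_WEIGHTS",
    "REACTIVITY_SCORE_MAP",
    "KNOWN_PEPTIDES",
    "bbb_rule_score",
    "cns_compliance",
    "bbb_class_from_probability",
    "bbb_class_from_rule_score",
    "pgp_liability",
    "reactivity_risk",
    "tractability_class",
    "feasibility_and_timeline",
    "safety_profile",
    "classify_modality",
    "medchem_penalty",
    "modality_adjusted_score",
    "evidence_level",
    "rank_within_modality",
]

#: Criterion id -> (weight, predicate description). Max total score 6.0.
BBB_CRITERIA_WEIGHTS: Mapping[str, float] = {
    "mw": 1.0,       # molecular weight <= 450 Da
    "logp": 2.0,     # 1.5 <= LogP <= 3.5
    "psa": 1.0,      # polar surface area <= 70 A^2
    "hbd": 0.5,      # hydrogen bond donors <= 3
    "hba": 0.5,      # hydrogen bond acceptors <= 7
    "n_plus_o": 1.0, # total N + O atoms <= 5
}

#: Numeric reactivity penalty per risk level (feeds the medchem penalty).
REACTIVITY_SCORE_MAP: Mapping[str, float] = {
    "Low": 0.1,
    "Moderate": 0.4,
    "High": 0.7,
    "VeryHigh": 1.0,
}

#: Default structural-alert table: flag -> risk level.
DEFAULT_ALERT_TABLE: Mapping[str, str] = {
    "protein_crosslinker": "High",
    "michael_acceptor": "High",
    "epoxide": "High",
    "acyl_halide": "VeryHigh",
    "electrophile": "Moderate",
    "nitroaromatic": "Moderate",
    "quinone": "Moderate",
    "aldehyde": "Moderate",
}

#: Peptide therapeutics classified as peptides regardless of molecular weight.
KNOWN_PEPTIDES: frozenset[str] = frozenset({"TROFINETIDE", "EXENATIDE", "LIRAGLUTIDE"})

_BIOLOGIC_SUFFIXES = ("-MAB", "-ZUMAB", "-CEPT", "-TINIB")
_PEPTIDE_SUFFIXES = ("-TIDE", "-PRESSIN")

_RISK_ORDER = {"Low": 0, "Moderate": 1, "High": 2, "VeryHigh": 3}

_FEASIBILITY_BY_CLASS = {"I": "High", "II": "ModerateHigh", "III": "Moderate", "IV": "Low"}


@dataclass(frozen=True)
class PhyschemProfile:
    """Per-drug physicochemical descriptors.

    ``n_plus_o`` (total nitrogen + oxygen atoms) is optional; when absent the
    acceptor count stands in for it and the assessment is marked approximated.
    """

    drug: str
    mw: float
    logp: float
    psa: float
    hbd: int
    hba: int
    rotatable_bonds: int | None = None
    n_plus_o: int | None = None
    reactivity_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.drug}: molecular weight must be positive")
        for fieldname in ("hbd", "hba"):
            if getattr(self, fieldname) < 0:
                raise ValueError(f"{self.drug}: {fieldname} must be nonnegative")


@dataclass
class BBBAssessment:
    rule_score: float
    violations: list[str]
    rule_class: str
    approximated: bool = False
    ml_probability: float | None = None
    ml_class: str | None = None

    @property
    def cns_compliant(self) -> bool:
        return not self.violations


@dataclass
class TractabilityAssessment:
    reactivity_risk: str
    reactivity_score: float
    tractability: str
    feasibility: str
    timeline: str
    pgp_liability: str
    safety_profile: str


@dataclass
class CandidateAnnotation:
    drug: str
    approved: bool = False
    known_peptide: bool = False
    peptidic_flag: bool = False
    mechanistic_pathway_tag: bool = False


@dataclass
class ModalityAdjustedScore:
    drug: str
    modality: str
    network_combined: float
    penalty: float
    adjusted: float
    evidence_level: str = "Speculative"
    ml_probability: float = 0.0
    direct_score: float = 0.0
    rank_in_modality: int | None = None


def bbb_rule_score(p: PhyschemProfile) -> BBBAssessment:
    """Six-criterion weighted BBB penetration score (maximum 6.0).

    Earns 1.0 for MW <= 450 Da, 2.0 for 1.5 <= LogP <= 3.5, 1.0 for
    PSA <= 70 A^2, 0.5 for HBD <= 3, 0.5 for HBA <= 7, and 1.0 for
    N+O count <= 5 (approximated by HBA when the atom count is missing).
    The rule class follows the score bands: >=5 High, [4,5) ModerateHigh,
    [3,4) Moderate, [2,3) Low, <2 VeryLow.
    """
    for name in ("mw", "logp", "psa", "hbd", "hba"):
        if getattr(p, name) is None:
            raise ValueError(f"{p.drug}: missing mandatory descriptor {name!r}")
    approximated = p.n_plus_o is None
    n_plus_o = p.hba if approximated else p.n_plus_o
    passed = {
        "mw": p.mw <= 450.0,
        "logp": 1.5 <= p.logp <= 3.5,
        "psa": p.psa <= 70.0,
        "hbd": p.hbd <= 3,
        "hba": p.hba <= 7,
        "n_plus_o": n_plus_o <= 5,
    }
    score = sum(BBB_CRITERIA_WEIGHTS[c] for c, ok in passed.items() if ok)
    violations = [c for c, ok in passed.items() if not ok]
    return BBBAssessment(
        rule_score=score,
        violations=violations,
        rule_class=bbb_class_from_rule_score(score),
        approximated=approximated,
    )


def bbb_class_from_rule_score(score: float) -> str:
    """Band the rule score; boundaries are inclusive on the lower edge."""
    if score >= 5.0:
        return "High"
    if score >= 4.0:
        return "ModerateHigh"
    if score >= 3.0:
        return "Moderate"
    if score >= 2.0:
        return "Low"
    return "VeryLow"


def cns_compliance(p: PhyschemProfile) -> bool:
    """True iff the profile simultaneously satisfies all six BBB criteria."""
    return bbb_rule_score(p).cns_compliant


def bbb_class_from_probability(pml: float) -> str:
    """Band a supervised BBB penetration probability.

    High (P >= 0.8), ModerateHigh (0.6 <= P < 0.8), Moderate (0.4 <= P < 0.6),
    Low (0.2 <= P < 0.4), VeryLow (P < 0.2).
    """
    if not 0.0 <= pml <= 1.0:
        raise ValueError(f"probability out of range: {pml}")
    if pml >= 0.8:
        return "High"
    if pml >= 0.6:
        return "ModerateHigh"
    if pml >= 0.4:
        return "Moderate"
    if pml >= 0.2:
        return "Low"
    return "VeryLow"


def pgp_liability(mw: float, logp: float, hba: int) -> str:
    """P-glycoprotein efflux liability from three structural risk factors.

    Risk factors: MW > 400 Da, LogP > 3.0, HBA >= 8. Zero factors -> Low,
    one -> Moderate, two or more -> High.
    """
    factors = sum([mw > 400.0, logp > 3.0, hba >= 8])
    if factors == 0:
        return "Low"
    if factors == 1:
        return "Moderate"
    return "High"


def reactivity_risk(
    flags: Sequence[str] | frozenset[str],
    alert_table: Mapping[str, str] | None = None,
    score_map: Mapping[str, float] | None = None,
) -> tuple[str, float]:
    """Maximum structural-alert risk level and its numeric penalty score.

    Unknown flags raise a warning and are ignored; a compound with no matched
    alerts is Low risk.
    """
    alert_table = DEFAULT_ALERT_TABLE if alert_table is None else alert_table
    score_map = REACTIVITY_SCORE_MAP if score_map is None else score_map
    level = "Low"
    for flag in flags:
        if flag not in alert_table:
            warnings.warn(f"unknown reactivity flag {flag!r} ignored", stacklevel=2)
            continue
        candidate = alert_table[flag]
        if _RISK_ORDER[candidate] > _RISK_ORDER[level]:
            level = candidate
    return level, score_map[level]


def tractability_class(bbb_class: str, reactivity: str, mw: float) -> str:
    """Four-class development tractability.

    The three criteria are favorable BBB class (High or ModerateHigh),
    acceptable reactivity (Low or Moderate), and MW <= 450 Da. All three met
    -> Class I; exactly two -> Class II; otherwise Class IV when the BBB class
    is VeryLow, else Class III.
    """
    met = sum(
        [
            bbb_class in ("High", "ModerateHigh"),
            reactivity in ("Low", "Moderate"),
            mw <= 450.0,
        ]
    )
    if met == 3:
        return "I"
    if met == 2:
        return "II"
    return "IV" if bbb_class == "VeryLow" else "III"


def feasibility_and_timeline(tractability: str, approved: bool) -> tuple[str, str]:
    """Development feasibility and clinical-translation timeline.

    Feasibility follows the tractability class directly. Approved Class I
    compounds are immediate (0-1 year) opportunities; experimental Class I
    compounds are short-term (1-3 years); Classes II/III map to medium/long
    term and Class IV to the research phase.
    """
    if tractability not in _FEASIBILITY_BY_CLASS:
        raise ValueError(f"unknown tractability class {tractability!r}")
    feasibility = _FEASIBILITY_BY_CLASS[tractability]
    if tractability == "I":
        timeline = "Immediate" if approved else "ShortTerm"
    elif tractability == "II":
        timeline = "MediumTerm"
    elif tractability == "III":
        timeline = "LongTerm"
    else:
        timeline = "Research"
    return feasibility, timeline


def safety_profile(reactivity: str, cns_compliant: bool) -> str:
    """Three-class safety stratification.

    High or VeryHigh reactivity dominates (HighRisk); Low reactivity with full
    CNS compliance is SafeForCNS; everything else is LowRisk.
    """
    if reactivity in ("High", "VeryHigh"):
        return "HighRisk"
    if reactivity == "Low" and cns_compliant:
        return "SafeForCNS"
    return "LowRisk"


def classify_modality(p: PhyschemProfile, ann: CandidateAnnotation) -> str:
    """Assign a therapeutic modality: small_molecule, peptide, or biologic.

    Precedence: curated known peptides first; then biologic nomenclature
    suffixes or MW > 1500 Da; then the 450-1500 Da window with peptidic
    evidence (suffix or annotation flag); otherwise small molecule.
    """
    name = p.drug.upper()
    if ann.known_peptide or name in KNOWN_PEPTIDES:
        return "peptide"
    if name.endswith(_BIOLOGIC_SUFFIXES) or p.mw > 1500.0:
        return "biologic"
    if 450.0 < p.mw <= 1500.0 and (
        name.endswith(_PEPTIDE_SUFFIXES) or ann.peptidic_flag
    ):
        return "peptide"
    return "small_molecule"


def medchem_penalty(ml_probability: float, reactivity_score: float) -> float:
    """BBB/reactivity penalty: 0.3*(1 - P_BBB) + 0.2*reactivity, in [0, 0.5]."""
    if not 0.0 <= ml_probability <= 1.0:
        raise ValueError("ml_probability must be in [0, 1]")
    if not 0.0 <= reactivity_score <= 1.0:
        raise ValueError("reactivity_score must be in [0, 1]")
    return 0.3 * (1.0 - ml_probability) + 0.2 * reactivity_score


_MODALITY_PENALTY_MULTIPLIER = {"small_molecule": 1.0, "peptide": 0.5, "biologic": 0.2}


def modality_adjusted_score(combined: float, penalty: float, modality: str) -> float:
    """Apply the modality-specific penalty multiplier to the network score.

    Small molecules take the full penalty; peptides half of it (transporter-
    mediated delivery relaxes passive-diffusion criteria); biologics one
    fifth (receptor-mediated transcytosis largely bypasses them).
    """
    if modality not in _MODALITY_PENALTY_MULTIPLIER:
        raise ValueError(f"unknown modality {modality!r}")
    return combined * (1.0 - _MODALITY_PENALTY_MULTIPLIER[modality] * penalty)


def evidence_level(
    ann: CandidateAnnotation, evidence_table: Mapping[str, str] | None = None
) -> str:
    """Disease-specific evidence tier from a curated annotation table.

    Levels: Established (approved for the disease), Clinical, Preclinical,
    Mechanistic (pathway rationale only), Speculative (network proximity
    only). Drugs absent from the table default to Mechanistic when a pathway
    tag exists, else Speculative.
    """
    table = {k.upper(): v for k, v in (evidence_table or {}).items()}
    if ann.drug.upper() in table:
        return table[ann.drug.upper()]
    return "Mechanistic" if ann.mechanistic_pathway_tag else "Speculative"


def rank_within_modality(
    candidates: Sequence[ModalityAdjustedScore],
) -> dict[str, list[ModalityAdjustedScore]]:
    """Rank candidates separately within each therapeutic modality.

    Descending adjusted score; ties broken by higher BBB probability for
    small molecules and peptides, by higher direct-interaction score for
    biologics, then by lexicographic drug name. Ranks are written back onto
    the candidate objects.
    """
    by_modality: dict[str, list[ModalityAdjustedScore]] = {}
    for c in candidates:
        by_modality.setdefault(c.modality, []).append(c)
    for modality, group in by_modality.items():
        if modality == "biologic":
            key = lambda c: (-c.adjusted, -c.direct_score, c.drug)
        else:
            key = lambda c: (-c.adjusted, -c.ml_probability, c.drug)
        group.sort(key=key)
        for i, c in enumerate(group, start=1):
            c.rank_in_modality = i
    return by_modality


def assess_candidates(
    profiles: Sequence[PhyschemProfile],
    network_scores: pd.DataFrame,
    annotations: Mapping[str, CandidateAnnotation] | None = None,
    ml_probabilities: Mapping[str, float] | None = None,
    evidence_table: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Full per-drug medicinal-chemistry assessment table.

    Joins physicochemical profiles with network combined scores, applies every
    rule-based assessment, the penalty and modality adjustment, and the
    modality-stratified ranking. ``ml_probabilities`` supplies supervised BBB
    probabilities; drugs without one fall back to the rule class for
    tractability and take probability 0.5 in the penalty (neutral prior).
    """
    annotations = annotations or {}
    ml_probabilities = {k.upper(): v for k, v in (ml_probabilities or {}).items()}
    scores = network_scores.set_index("drug")
    rows = []
    adjusted_objs = []
    for p in profiles:
        name = p.drug.upper()
        ann = annotations.get(name, CandidateAnnotation(drug=name))
        bbb = bbb_rule_score(p)
        pml = ml_probabilities.get(name)
        if pml is not None:
            bbb.ml_probability = pml
            bbb.ml_class = bbb_class_from_probability(pml)
        react_level, react_score = reactivity_risk(p.reactivity_flags)
        bbb_for_tract = bbb.ml_class if bbb.ml_class is not None else bbb.rule_class
        tract = tractability_class(bbb_for_tract, react_level, p.mw)
        feas, timeline = feasibility_and_timeline(tract, ann.approved)
        safety = safety_profile(react_level, bbb.cns_compliant)
        pgp = pgp_liability(p.mw, p.logp, p.hba)
        modality = classify_modality(p, ann)
        penalty = medchem_penalty(0.5 if pml is None else pml, react_score)
        combined = float(scores.loc[name, "combined"]) if name in scores.index else 0.0
        direct = float(scores.loc[name, "direct"]) if name in scores.index else 0.0
        adjusted = modality_adjusted_score(combined, penalty, modality)
        evid = evidence_level(ann, evidence_table)
        adjusted_objs.append(
            ModalityAdjustedScore(
                drug=name,
                modality=modality,
                network_combined=combined,
                penalty=penalty,
                adjusted=adjusted,
                evidence_level=evid,
                ml_probability=0.0 if pml is None else pml,
                direct_score=direct,
            )
        )
        rows.append(
            {
                "drug": name,
                "status": "Approved" if ann.approved else "Experimental",
                "network_score": combined,
                "medchem_score": adjusted,
                "mw": p.mw,
                "logp": p.logp,
                "psa": p.psa,
                "hbd": p.hbd,
                "hba": p.hba,
                "bbb_rule_score": bbb.rule_score,
                "bbb_rule_class": bbb.rule_class,
                "cns_compliant": bbb.cns_compliant,
                "bbb_ml_prob": pml,
                "bbb_ml_class": bbb.ml_class,
                "pgp": pgp,
                "tractability": tract,
                "feasibility": feas,
                "timeline": timeline,
                "reactivity": react_level,
                "safety": safety,
                "modality": modality,
                "penalty": penalty,
                "ad_evidence": evid,
            }
        )
    rank_within_modality(adjusted_objs)
    ranks = {c.drug: c.rank_in_modality for c in adjusted_objs}
    table = pd.DataFrame(rows)
    table["rank_in_modality"] = table["drug"].map(ranks)
    return table.sort_values(
        ["modality", "rank_in_modality"], kind="mergesort"
    ).reset_index(drop=True)
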