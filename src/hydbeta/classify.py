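"""Residue-fingerprint classification of beta subunits: BF vs non-BF.

Flavin-containing beta subunits (HydB / NuoF / Nqo1 homologs) of
NADH-dependent [FeFe]-hydrogenases and formate dehydrogenases fall into two
functional groups: electron-bifurcating (BF) enzymes, which couple NADH and
ferredoxin oxidation, and non-bifurcating (non-BF) enzymes that run on NADH
alone. The groups are separable by conserved residues at a handful of
positions stated in the *T. maritima* HydB reference frame:

====================  ==================  =============  ==================
criterion             HydB positions      BF residues    non-BF residues
====================  ==================  =============  ==================
NADH site             232                 A or E         T or S
NADH site             234                 M              K, S or A
FMN site              367                 F              Y
SLBB domain           427-431             GGPSG motif    anything else
====================  ==================  =============  ==================

A query is aligned to the reference scaffold, the fingerprint positions are
read off through the position map, each rule is evaluated, and an overall
verdict is taken by unanimity of the non-indeterminate rules with a quorum
of at least two. A gap at any rule position makes that rule indeterminate
(absence of evidence), as does a residue outside both allowed sets.
Cluster-count differences are attached as advisory support but never decide
the verdict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from collections import Counter

from .align import GAP, SubstitutionScheme, map_query, residues_at
from .fescan import DEFAULT_MOTIF_CONFIG, extra_cluster_count, scan_clusters
from .records import ProteinRecord

logger = logging.getLogger(__name__)

BF = "BF"
NONBF = "nonBF"
AMBIGUOUS = "ambiguous"
INDETERMINATE = "indeterminate"

#: Minimum alignment identity (matched columns / alignment columns) below
#: which classification is refused rather than risked.
DEFAULT_IDENTITY_FLOOR = 0.15


@dataclass(frozen=True)
class FingerprintRule:
    """One diagnostic criterion in reference coordinates.

    Either both ``bf_allowed`` and ``nonbf_allowed`` are residue sets (one
    per reference position semantics: the observed string must consist of
    allowed residues), or ``bf_motif`` is an exact motif string and any
    gap-free non-match counts as non-BF.
    """

    name: str
    ref_positions: tuple
    bf_allowed: frozenset = frozenset()
    nonbf_allowed: frozenset = frozenset()
    bf_motif: str = ""

    def __post_init__(self) -> None:
        pos = list(self.ref_positions)
        if not pos or any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"rule {self.name}: ref_positions must be non-empty, increasing")
        if self.bf_motif:
            if len(self.bf_motif) != len(pos):
                raise ValueError(f"rule {self.name}: motif length != number of positions")
        else:
            if not self.bf_allowed:
                raise ValueError(f"rule {self.name}: no BF residues or motif given")
            if self.bf_allowed & self.nonbf_allowed:
                raise ValueError(f"rule {self.name}: BF and non-BF residue sets overlap")

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "ref_positions": list(self.ref_positions)}
        if self.bf_motif:
            d["bf_motif"] = self.bf_motif
        else:
            d["bf_allowed"] = sorted(self.bf_allowed)
            d["nonbf_allowed"] = sorted(self.nonbf_allowed)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintRule":
        return cls(
            name=d["name"],
            ref_positions=tuple(d["ref_positions"]),
            bf_allowed=frozenset(d.get("bf_allowed", ())),
            nonbf_allowed=frozenset(d.get("nonbf_allowed", ())),
            bf_motif=d.get("bf_motif", ""),
        )


@dataclass(frozen=True)
class CriterionEvidence:
    """Observed residues and per-rule verdict for one sequence."""

    rule_name: str
    observed: str
    verdict: str

    def __post_init__(self) -> None:
        if GAP in self.observed and self.verdict != INDETERMINATE:
            raise ValueError("gapped observation must be indeterminate")

    def to_dict(self) -> dict:
        return {"rule_name": self.rule_name, "observed": self.observed, "verdict": self.verdict}


@dataclass(frozen=True)
class ClassificationResult:
    """Per-sequence verdict with its evidence trail."""

    seq_id: str
    evidence: tuple
    fes_support: int
    overall: str
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "seq_id": self.seq_id,
            "evidence": [e.to_dict() for e in self.evidence],
            "fes_support": self.fes_support,
            "overall": self.overall,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationResult":
        return cls(
            seq_id=d["seq_id"],
            evidence=tuple(
                CriterionEvidence(e["rule_name"], e["observed"], e["verdict"])
                for e in d["evidence"]
            ),
            fes_support=d["fes_support"],
            overall=d["overall"],
            note=d.get("note", ""),
        )


def default_rules() -> list[FingerprintRule]:
    """The four shipped diagnostic criteria (immutable defaults).

    The two NADH-site positions are separate rules internally; together with
    the FMN-site rule and the SLBB motif they realise the three differential
    sequence regions, and the (advisory) cluster count is the fourth
    published criterion.
    """
    return [
        FingerprintRule(
            name="nadh_site_232", ref_positions=(232,),
            bf_allowed=frozenset("AE"), nonbf_allowed=frozenset("TS"),
        ),
        FingerprintRule(
            name="nadh_site_234", ref_positions=(234,),
            bf_allowed=frozenset("M"), nonbf_allowed=frozenset("KSA"),
        ),
        FingerprintRule(
            name="fmn_site_367", ref_positions=(367,),
            bf_allowed=frozenset("F"), nonbf_allowed=frozenset("Y"),
        ),
        FingerprintRule(
            name="slbb_427_431", ref_positions=(427, 428, 429, 430, 431),
            bf_motif="GGPSG",
        ),
    ]


def save_rules(rules, path) -> None:
    """Serialise rules to a JSON rules file."""
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in rules], fh, indent=1)


def load_rules(path) -> list[FingerprintRule]:
    """Load rules from a JSON rules file (user-extensible)."""
    with open(path) as fh:
        return [FingerprintRule.from_dict(d) for d in json.load(fh)]


def evaluate_criterion(rule: FingerprintRule, observed_residues) -> CriterionEvidence:
    """Evaluate one rule on the residues read off at its reference positions."""
    obs = "".join(observed_residues)
    if len(obs) != len(rule.ref_positions):
        raise ValueError(
            f"rule {rule.name}: expected {len(rule.ref_positions)} residues, got {len(obs)}"
        )
    if GAP in obs:
        verdict = INDETERMINATE
    elif rule.bf_motif:
        verdict = BF if obs == rule.bf_motif else NONBF
    elif all(c in rule.bf_allowed for c in obs):
        verdict = BF
    elif all(c in rule.nonbf_allowed for c in obs):
        verdict = NONBF
    else:
        verdict = INDETERMINATE
    return CriterionEvidence(rule_name=rule.name, observed=obs, verdict=verdict)


def overall_verdict(evidence) -> str:
    """Unanimity of non-indeterminate rule verdicts with a quorum of >= 2."""
    votes = [e.verdict for e in evidence if e.verdict != INDETERMINATE]
    if len(votes) >= 2 and all(v == BF for v in votes):
        return BF
    if len(votes) >= 2 and all(v == NONBF for v in votes):
        return NONBF
    return AMBIGUOUS


def classify_sequence(query: ProteinRecord, reference: ProteinRecord,
                      rules=None, scheme: SubstitutionScheme | None = None,
                      identity_floor: float = DEFAULT_IDENTITY_FLOOR,
                      motif_config=DEFAULT_MOTIF_CONFIG,
                      _reference_annotations=None) -> ClassificationResult:
    """Classify one query against the reference scaffold.

    Aligns the query globally to the reference, builds the position map,
    evaluates every rule and attaches the cluster-count difference relative
    to the reference as advisory support. If the alignment identity falls
    below ``identity_floor`` the result is a refusal: overall ambiguous,
    every rule indeterminate, with a note saying why.
    """
    if rules is None:
        rules = default_rules()
    aln, pmap = map_query(query, reference, scheme)
    if _reference_annotations is None:
        _reference_annotations = scan_clusters(reference, motif_config)
    fes = extra_cluster_count(scan_clusters(query, motif_config), _reference_annotations)
    if aln.identity < identity_floor:
        logger.warning(
            "refusing to classify %s: alignment identity %.3f below floor %.3f",
            query.id, aln.identity, identity_floor,
        )
        evidence = tuple(
            CriterionEvidence(r.name, GAP * len(r.ref_positions), INDETERMINATE)
            for r in rules
        )
        return ClassificationResult(
            seq_id=query.id, evidence=evidence, fes_support=fes, overall=AMBIGUOUS,
            note=f"refused: alignment identity {aln.identity:.3f} < floor {identity_floor}",
        )
    evidence = tuple(
        evaluate_criterion(r, residues_at(query, pmap, r.ref_positions)) for r in rules
    )
    return ClassificationResult(
        seq_id=query.id, evidence=evidence, fes_support=fes,
        overall=overall_verdict(evidence),
    )


def classify_batch(records, reference: ProteinRecord, rules=None,
                   scheme: SubstitutionScheme | None = None,
                   identity_floor: float = DEFAULT_IDENTITY_FLOOR,
                   motif_config=DEFAULT_MOTIF_CONFIG):
    """Classify records independently; returns (results, summary counts).

    Results keep the input order; per-record refusals are recorded, never
    raised. The summary counts every overall class that occurs.
    """
    records = list(records)
    if not records:
        raise ValueError("classify_batch: empty record list")
    if rules is None:
        rules = default_rules()
    ref_annotations = scan_clusters(reference, motif_config)
    results = [
        classify_sequence(
            rec, reference, rules=rules, scheme=scheme,
            identity_floor=identity_floor, motif_config=motif_config,
            _reference_annotations=ref_annotations,
        )
        for rec in records
    ]
    summary = Counter(r.overall for r in results)
    return results, dict(summary)
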