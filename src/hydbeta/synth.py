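"""Seeded generator of beta-subunit-like sequences with planted truth.

Real beta subunits cannot be bundled with the package, so every downstream
operation (position mapping, fingerprint classification, Fe-S scanning,
phylogeny) is exercised on synthetic sequences whose ground truth is known
by construction:

* a random reference scaffold of ~600 residues (beta subunits run ~420-620)
  carries the BF fingerprint at the HydB-frame positions (232, 234, 367 and
  the GGPSG motif at 427-431);
* planted sequences rewrite the fingerprint positions with residues drawn
  from the target class's allowed sets, plant a configurable number of Fe-S
  cysteine motifs in reserved zones, then mutate the background down to a
  requested identity and optionally apply short indels;
* the background alphabet excludes cysteine, so every C in a generated
  sequence is a planted motif anchor — scans are exactly checkable;
* indels are kept out of a +/-5 guard band around fingerprint positions and
  out of motif spans, so fingerprint positions survive re-alignment and
  motif counts survive mutation;
* a single integer seed drives one random stream per sequence, making every
  fixture bit-reproducible.

What this emulates is the *statistical* structure of the published
comparison — class-consistent fingerprints on a shared scaffold with
divergent background — not real evolutionary history: background
substitutions are uniform over the 19 non-cysteine residues, with no
substitution-matrix or site-rate bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fescan import FES2, FES4, HCLUSTER
from .records import ProteinRecord, write_fasta

#: Background alphabet: the 19 standard residues other than cysteine.
BACKGROUND_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

#: HydB-frame fingerprint positions and the class-allowed residues.
BF_SITE_RESIDUES = {232: "AE", 234: "M", 367: "F"}
NONBF_SITE_RESIDUES = {232: "TS", 234: "KSA", 367: "Y"}
SLBB_POSITIONS = (427, 428, 429, 430, 431)
SLBB_BF_MOTIF = "GGPSG"
FINGERPRINT_POSITIONS = (232, 234, 367) + SLBB_POSITIONS

#: Indels are excluded within this many residues of a fingerprint position.
GUARD_BAND = 5

#: Minimum cysteine-free residues between consecutive planted motifs, so no
#: spacing window (max 40) can bridge two motifs.
MOTIF_SEPARATION = 42

#: Spacer windows used when planting (FeS2 tail capped at 30 so motifs fit
#: the reserved zones; still inside the scanner's 20-40 acceptance window).
_PLANT_WINDOWS = {
    FES4: ((2, 2), (2, 2), (2, 4)),
    FES2: ((4, 6), (1, 3), (20, 30)),
    HCLUSTER: ((2, 2), (2, 2), (5, 24)),
}

#: Default planted cluster counts: BF subunits carry extra cluster domains.
DEFAULT_CLUSTER_COUNTS = {
    "BF": {FES4: 4, FES2: 2},
    "nonBF": {FES4: 2, FES2: 1},
}


@dataclass(frozen=True)
class Scaffold:
    """Reference scaffold plus its frame annotation."""

    record: ProteinRecord
    fingerprint_positions: tuple = FINGERPRINT_POSITIONS
    regions: tuple = ()  # plantable cysteine-free segments, 1-based inclusive


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything that was planted into one synthetic sequence."""

    id: str
    planted_class: str
    planted_residues: dict
    background_identity: float
    planted_cluster_counts: dict
    seed: int
    realized_identity: float = 1.0


def _guard_positions() -> frozenset:
    out = set()
    for p in FINGERPRINT_POSITIONS:
        out.update(range(p - GUARD_BAND, p + GUARD_BAND + 1))
    return frozenset(out)


_GUARDS = _guard_positions()


def _plantable_regions(length: int) -> tuple:
    regions = []
    start = 1
    for pos in sorted(_GUARDS) + [length + 1]:
        if pos > start:
            regions.append((start, pos - 1))
        start = max(start, pos + 1)
    # merge the sweep above into maximal unguarded segments
    merged = []
    for s, e in regions:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple((s, e) for s, e in merged if e - s >= 10)


def make_reference_scaffold(length: int = 600, seed: int = 0) -> Scaffold:
    """Random BF-patterned scaffold standing in for the HydB reference frame.

    Deterministic per seed; different seeds share the fingerprint positions
    but differ everywhere else. The background contains no cysteine.
    """
    if length < 450:
        raise ValueError("scaffold must be at least 450 residues (position 431 + margin)")
    rng = np.random.default_rng(seed)
    bg = np.array(list(BACKGROUND_ALPHABET))
    residues = list(rng.choice(bg, size=length))
    for pos, allowed in BF_SITE_RESIDUES.items():
        residues[pos - 1] = allowed[0]
    for pos, aa in zip(SLBB_POSITIONS, SLBB_BF_MOTIF):
        residues[pos - 1] = aa
    record = ProteinRecord(id=f"scaffold_{seed}", residues="".join(residues),
                           description="synthetic HydB-frame reference scaffold")
    return Scaffold(record=record, regions=_plantable_regions(length))


def _place_motifs(residues: list, counts: dict, regions, rng):
    """Write motif anchor cysteines into reserved zones; returns spans and anchors."""
    motifs = []
    for ctype in (FES4, FES2, HCLUSTER):
        motifs.extend([ctype] * counts.get(ctype, 0))
    placed = []  # (type, start, end, anchors)
    region_iter = iter(regions)
    region = next(region_iter, None)
    pos = region[0] if region else None
    for ctype in motifs:
        gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in _PLANT_WINDOWS[ctype]]
        span = 1 + sum(g + 1 for g in gaps)
        while region is not None and pos + span - 1 > region[1]:
            region = next(region_iter, None)
            if region is not None:
                pos = max(region[0], pos)
        if region is None:
            raise ValueError("scaffold too short for requested motif counts")
        anchors = [pos]
        for g in gaps:
            anchors.append(anchors[-1] + g + 1)
        for a in anchors:
            residues[a - 1] = "C"
        placed.append((ctype, anchors[0], anchors[-1], tuple(anchors)))
        pos = anchors[-1] + MOTIF_SEPARATION
    return placed


def plant_sequence(scaffold: Scaffold, cls: str, background_identity: float = 0.8,
                   indel_rate: float = 0.0, seed: int = 0,
                   cluster_counts: dict | None = None,
                   record_id: str | None = None):
    """Generate one sequence of the given class; returns (record, truth).

    Fingerprint positions receive residues sampled uniformly from the
    class's allowed sets; background positions are substituted (never to
    cysteine) at the rate that brings overall identity to the target; short
    indels (1-3 residues) are applied outside guard bands and motif spans.
    """
    if cls not in ("BF", "nonBF"):
        raise ValueError("class must be BF or nonBF")
    if not 0 < background_identity <= 1:
        raise ValueError("background_identity must lie in (0, 1]")
    if indel_rate < 0:
        raise ValueError("indel_rate must be >= 0")
    rng = np.random.default_rng(seed)
    base = scaffold.record.residues
    residues = list(base)
    length = len(residues)

    planted: dict = {}
    sites = BF_SITE_RESIDUES if cls == "BF" else NONBF_SITE_RESIDUES
    for pos, allowed in sites.items():
        aa = allowed[int(rng.integers(len(allowed)))]
        residues[pos - 1] = aa
        planted[pos] = aa
    if cls == "BF":
        slbb = SLBB_BF_MOTIF
    else:
        while True:
            slbb = "".join(
                BACKGROUND_ALPHABET[int(k)]
                for k in rng.integers(len(BACKGROUND_ALPHABET), size=len(SLBB_POSITIONS))
            )
            if slbb != SLBB_BF_MOTIF:
                break
    for pos, aa in zip(SLBB_POSITIONS, slbb):
        residues[pos - 1] = aa
        planted[pos] = aa

    if cluster_counts is None:
        cluster_counts = DEFAULT_CLUSTER_COUNTS[cls]
    placed = _place_motifs(residues, cluster_counts, scaffold.regions, rng)
    protected = set(FINGERPRINT_POSITIONS)
    motif_spans = []
    for _, start, end, anchors in placed:
        protected.update(anchors)
        motif_spans.append((start, end))

    # Substitutions: overall identity to the scaffold (planted differences
    # included) is driven to the target with an exact mismatch count, so the
    # realised identity is deterministic up to rounding.
    mutable = [p for p in range(1, length + 1) if p not in protected]
    mismatch0 = sum(a != b for a, b in zip(residues, base))
    n_sub = int(round((1.0 - background_identity) * length)) - mismatch0
    n_sub = max(0, min(n_sub, len(mutable)))
    for pos in rng.choice(mutable, size=n_sub, replace=False):
        current = residues[pos - 1]
        alternatives = [c for c in BACKGROUND_ALPHABET if c != current]
        residues[pos - 1] = alternatives[int(rng.integers(len(alternatives)))]
    realized = sum(a == b for a, b in zip(residues, base)) / length

    if indel_rate > 0:
        eligible = np.array([
            p for p in range(1, length + 1)
            if p not in _GUARDS and not any(s <= p <= e for s, e in motif_spans)
        ])
        events = eligible[rng.random(len(eligible)) < indel_rate]
        elig_set = set(int(p) for p in eligible)
        for pos in sorted((int(p) for p in events), reverse=True):
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion after pos
                insert = [
                    BACKGROUND_ALPHABET[int(k)]
                    for k in rng.integers(len(BACKGROUND_ALPHABET), size=size)
                ]
                residues[pos:pos] = insert
            else:  # deletion of an eligible block starting at pos
                if all((pos + k) in elig_set for k in range(size)):
                    del residues[pos - 1: pos - 1 + size]

    rec_id = record_id if record_id is not None else f"{cls}_{seed}"
    record = ProteinRecord(id=rec_id, residues="".join(residues),
                           description=f"synthetic {cls} plant")
    truth = SyntheticTruth(
        id=rec_id, planted_class=cls, planted_residues=planted,
        background_identity=background_identity,
        planted_cluster_counts=dict(cluster_counts), seed=seed,
        realized_identity=realized,
    )
    return record, truth


def mutation_ladder(scaffold: Scaffold, cls: str, identities, seed: int = 0,
                    cluster_counts: dict | None = None) -> list[ProteinRecord]:
    """One planted sequence mutated progressively along decreasing identities.

    Each rung adds substitutions to the same trajectory (never touching
    fingerprint or motif-anchor positions), so verdicts can be checked for
    monotone degradation: the planted class may fade to ambiguous but must
    never flip to the opposite class.
    """
    identities = sorted(identities, reverse=True)
    record, _ = plant_sequence(scaffold, cls, background_identity=1.0, seed=seed,
                               cluster_counts=cluster_counts)
    rng = np.random.default_rng(seed + 1)
    residues = list(record.residues)
    length = len(residues)
    protected = set(FINGERPRINT_POSITIONS) | {
        p for p in range(1, length + 1) if residues[p - 1] == "C"
    }
    remaining = [p for p in range(1, length + 1) if p not in protected]
    rng.shuffle(remaining)
    mutated = 0
    out = []
    for identity in identities:
        target = min(int(round((1.0 - identity) * length)), len(remaining))
        while mutated < target:
            pos = remaining[mutated]
            current = residues[pos - 1]
            alternatives = [c for c in BACKGROUND_ALPHABET if c != current]
            residues[pos - 1] = alternatives[int(rng.integers(len(alternatives)))]
            mutated += 1
        out.append(ProteinRecord(id=f"{record.id}_id{identity:.2f}",
                                 residues="".join(residues),
                                 description=f"ladder rung identity {identity:.2f}"))
    return out


def truth_table(truths) -> pd.DataFrame:
    """Tabular ground truth (one row per generated sequence)."""
    return pd.DataFrame(
        [
            {
                "id": t.id,
                "class": t.planted_class,
                "identity": t.background_identity,
                "realized_identity": round(t.realized_identity, 4),
                "planted_residues": ";".join(
                    f"{p}:{aa}" for p, aa in sorted(t.planted_residues.items())
                ),
                "cluster_counts": ";".join(
                    f"{k}:{v}" for k, v in sorted(t.planted_cluster_counts.items())
                ),
                "seed": t.seed,
            }
            for t in truths
        ]
    )


def generate_dataset(n_bf: int, n_nonbf: int, identity_range=(0.6, 0.9),
                     seed: int = 0, indel_rate: float = 0.0,
                     scaffold: Scaffold | None = None, out_prefix=None):
    """Generate a labeled dataset; returns (records, truths, scaffold).

    Reproducible per seed. With ``out_prefix`` the records are written to
    ``<prefix>.faa`` and the truth table to ``<prefix>.truth.tsv``.
    """
    if n_bf + n_nonbf < 1:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)
    if scaffold is None:
        scaffold = make_reference_scaffold(seed=seed)
    lo, hi = identity_range
    records, truths = [], []
    for cls, count in (("BF", n_bf), ("nonBF", n_nonbf)):
        for k in range(count):
            identity = float(rng.uniform(lo, hi))
            child_seed = int(rng.integers(2**31))
            rec, truth = plant_sequence(
                scaffold, cls, background_identity=identity,
                indel_rate=indel_rate, seed=child_seed,
                record_id=f"{cls}_{k:03d}",
            )
            records.append(rec)
            truths.append(truth)
    if out_prefix is not None:
        write_fasta(records, f"{out_prefix}.faa")
        truth_table(truths).to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
    return records, truths, scaffold


def generate_clade_dataset(n_bf: int = 6, n_nonbf: int = 6,
                           within_identity: float = 0.9,
                           between_identity: float = 0.65,
                           seed: int = 0, length: int = 460):
    """Two diverged classes for phylogeny tests; returns (records, labels, reference).

    The non-BF class descends from a scaffold diverged to ``between_identity``
    of the base scaffold, each member then diverging to ``within_identity``
    of its class scaffold — elevated between-class divergence without full
    tree-structured simulation. No Fe-S motifs are planted (irrelevant to
    distances and the sequences stay alignable).
    """
    rng = np.random.default_rng(seed)
    base = make_reference_scaffold(length=length, seed=int(rng.integers(2**31)))
    diverged_rec, _ = plant_sequence(
        base, "nonBF", background_identity=between_identity,
        seed=int(rng.integers(2**31)), cluster_counts={}, record_id="nonBF_scaffold",
    )
    nonbf_scaffold = Scaffold(record=diverged_rec, regions=base.regions)
    records, labels = [], {}
    for cls, count, scaf in (("BF", n_bf, base), ("nonBF", n_nonbf, nonbf_scaffold)):
        for k in range(count):
            rec, _ = plant_sequence(
                scaf, cls, background_identity=within_identity,
                seed=int(rng.integers(2**31)), cluster_counts={},
                record_id=f"{cls}_{k:03d}",
            )
            records.append(rec)
            labels[rec.id] = cls
    return records, labels, base.record
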