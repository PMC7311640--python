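"""Analytic biochemistry: masses, pI, activities, purification statistics.

The worked-example arithmetic that accompanies enzyme purification papers:
predicted molecular mass and isoelectric point from sequence,
extinction-coefficient specific activities (U = umol/min), purification
fold and yield tables, and per-subcomplex stoichiometry conversions (e.g.,
iron per heterotetramer vs per alpha-beta heterodimer).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight
from scipy.optimize import brentq

from .records import ProteinRecord

#: EMBOSS pKa values for ionisable groups; overridable per call.
DEFAULT_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class AssayMeasurement:
    """One spectrophotometric rate measurement."""

    delta_A_per_min: float
    epsilon_mM_cm: float
    path_cm: float = 1.0
    volume_ml: float = 1.0
    protein_mg: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.delta_A_per_min, self.epsilon_mM_cm, self.path_cm,
                self.volume_ml, self.protein_mg)
        if any(v <= 0 for v in vals):
            raise ValueError("all measurement fields must be strictly positive")


@dataclass(frozen=True)
class PurificationStep:
    """One row of a purification table."""

    name: str
    total_protein_mg: float
    total_activity_U: float

    def __post_init__(self) -> None:
        if self.total_protein_mg < 0 or self.total_activity_U < 0:
            raise ValueError("protein and activity must be non-negative")

    @property
    def specific_activity(self) -> float:
        if self.total_protein_mg <= 0:
            raise ValueError(f"step {self.name}: specific activity undefined without protein")
        return self.total_activity_U / self.total_protein_mg


def protein_mass_kda(seq: ProteinRecord | str) -> float:
    """Predicted molecular mass in kDa (average residue masses plus one water)."""
    residues = seq.residues if isinstance(seq, ProteinRecord) else seq
    if "X" in residues:
        raise ValueError("sequence contains X: mass undefined")
    return molecular_weight(residues, seq_type="protein") / 1000.0


def net_charge(residues: str, pH: float, pka_table: dict | None = None) -> float:
    """Henderson-Hasselbalch net charge of the peptide at the given pH."""
    pka = DEFAULT_PKA if pka_table is None else pka_table
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - pH))
    for aa in _POSITIVE:
        charge += residues.count(aa) / (1.0 + 10.0 ** (pH - pka[aa]))
    for aa in _NEGATIVE:
        charge -= residues.count(aa) / (1.0 + 10.0 ** (pka[aa] - pH))
    return charge


def theoretical_pi(seq: ProteinRecord | str, pka_table: dict | None = None) -> float:
    """Isoelectric point: the pH at which the net charge crosses zero.

    Solved by root bracketing on [0, 14]; the result depends on the pKa
    table used (EMBOSS values by default), as all pI predictors do.
    """
    residues = seq.residues if isinstance(seq, ProteinRecord) else seq
    return float(brentq(lambda ph: net_charge(residues, ph, pka_table), 0.0, 14.0,
                        xtol=1e-6))


def specific_activity(m: AssayMeasurement, stoich_factor: float = 1.0) -> float:
    """Specific activity in U/mg from a Beer-Lambert rate measurement.

    ``stoich_factor`` divides out multi-chromophore stoichiometries, e.g. 2
    for two one-electron viologen reductions per H2.
    """
    rate_umol_per_min = m.delta_A_per_min / (m.epsilon_mM_cm * m.path_cm) * m.volume_ml
    return rate_umol_per_min / m.protein_mg / stoich_factor


def purification_stats(steps) -> list[dict]:
    """Fold purification and yield of each step relative to the first.

    Returns one dict per step: name, specific_activity (U/mg), fold and
    yield_pct. Step 1 is fold 1.0, yield 100% by definition.
    """
    steps = list(steps)
    if not steps:
        raise ValueError("purification_stats: empty step list")
    first = steps[0]
    if first.total_protein_mg <= 0 or first.total_activity_U <= 0:
        raise ValueError("first step must have positive protein and activity")
    sa0 = first.specific_activity
    return [
        {
            "name": s.name,
            "specific_activity": s.specific_activity,
            "fold": s.specific_activity / sa0,
            "yield_pct": 100.0 * s.total_activity_U / first.total_activity_U,
        }
        for s in steps
    ]


def per_subcomplex(value_per_complex: float, subcomplexes_per_complex: int,
                   ndigits: int | None = None) -> float:
    """Convert a per-complex quantity to per-subcomplex (e.g. Fe per heterodimer).

    ``ndigits`` applies the reporting rounding policy (1 decimal in tables);
    by default the raw quotient is returned.
    """
    if subcomplexes_per_complex < 1:
        raise ValueError("subcomplexes_per_complex must be >= 1")
    value = value_per_complex / subcomplexes_per_complex
    return round(value, ndigits) if ndigits is not None else value
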