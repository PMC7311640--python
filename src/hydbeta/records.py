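"""Core sequence records and the formats the pipeline reads and writes.

The universal input unit is :class:`ProteinRecord`: an identifier plus an
uppercase amino-acid string over the 20 standard residues and ``X``.
FASTA input/output goes through Biopython; classification reports are
written as TSV or JSON with a fixed column order.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus X (unknown).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Ambiguity / nonstandard letters normalised to X on input.
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X"}


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    Parameters
    ----------
    id : str
        Unique token; must contain no whitespace.
    residues : str
        Uppercase sequence over the 20 amino-acid letters plus ``X``.
    description : str
        Free-text description (may be empty).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a whitespace-free token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledSet:
    """Protein records together with BF / nonBF / unknown labels."""

    records: list[ProteinRecord]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        missing = set(self.labels) - ids
        if missing:
            raise ValueError(f"labels refer to unknown ids: {sorted(missing)}")
        bad = set(self.labels.values()) - {"BF", "nonBF", "unknown"}
        if bad:
            raise ValueError(f"illegal labels: {sorted(bad)}")


def _normalise_residues(record_id: str, raw: str) -> str:
    seq = raw.upper().rstrip("*")
    for src, dst in _AMBIGUOUS.items():
        if src in seq:
            logger.warning("record %s: mapping ambiguity character %s -> X", record_id, src)
            seq = seq.replace(src, dst)
    return seq


def _locate_bad_line(path, record_id: str, bad_chars: set[str]) -> int:
    # Error path only: re-scan the raw text to name the offending line.
    with open(path) as fh:
        in_record = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and bad_chars & set(line.strip().upper()):
                return lineno
    return -1


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Residues are uppercased, terminal stop symbols (``*``) stripped and the
    ambiguity letters B, Z, U, O mapped to ``X`` with a logged warning.
    Any wrapping is accepted. Record order is preserved.

    Note that the protein alphabet is a superset of the nucleotide letters,
    so nucleotide-looking input is accepted as long as every character is a
    legal amino-acid letter; no guessing is performed.

    Raises
    ------
    FastaParseError
        If the file does not start with a header or contains residues
        outside the alphabet; the message names the line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(f"{path}: line {lineno}: expected FASTA header '>'")
            break
        else:
            raise FastaParseError(f"{path}: empty file")

    out: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        seq = _normalise_residues(rec.id, str(rec.seq))
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            lineno = _locate_bad_line(path, rec.id, bad)
            raise FastaParseError(
                f"{path}: line {lineno}: record {rec.id}: "
                f"illegal residue characters {sorted(bad)}"
            )
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id}: empty sequence")
        out.append(ProteinRecord(id=rec.id, residues=seq, description=rec.description))
    return out


def write_fasta(records, path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def _result_to_row(result) -> dict:
    row: dict = {"id": result.seq_id, "overall": result.overall}
    for ev in result.evidence:
        row[f"{ev.rule_name}_verdict"] = ev.verdict
        row[f"{ev.rule_name}_observed"] = ev.observed if ev.observed else None
    row["fes_support"] = result.fes_support
    return row


def write_report(results, path, format: str = "tsv") -> None:
    """Write classification results as a TSV table or JSON document.

    One row/object per sequence: id, overall class, per-criterion verdicts
    and observed residues, Fe-S support count. Columns follow the rule order
    of the first result; indeterminate/missing cells hold the literal token
    ``NA`` in TSV and ``null`` in JSON.
    """
    if not results:
        raise ValueError("write_report: empty results")
    if format == "tsv":
        frame = pd.DataFrame([_result_to_row(r) for r in results])
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([r.to_dict() for r in results], fh, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r}")


def fasta_string(records) -> str:
    """Render records as a FASTA-formatted string (60-column wrap)."""
    buf = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records],
        buf,
        "fasta",
    )
    return buf.getvalue()
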