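"""Two-tier unique peptide-to-protein mapping against FASTA databases.

Peptides are mapped by exact substring search against a primary (curated,
Swiss-Prot-style) database; a peptide matching exactly one primary protein is
assigned to it, a peptide matching several is discarded as ambiguous, and a
peptide matching none is re-searched against a secondary (TrEMBL-style)
database under the same uniqueness rule.  Shared peptides are discarded
rather than grouped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "ProteinDatabase",
    "PeptideAssignment",
    "read_fasta_database",
    "map_peptides_two_tier",
]


@dataclass
class ProteinDatabase:
    tier: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"empty {self.tier} database")
        for acc, seq in self.sequences.items():
            if not seq.isalpha() or not seq.isupper():
                raise ValueError(f"{acc}: sequences must be uppercase alphabetic")

    def matches(self, peptide: str, equate_il: bool = False) -> list[str]:
        """Accessions whose sequence contains the peptide as a substring."""
        pep = peptide.replace("I", "L") if equate_il else peptide
        hits = []
        for acc, seq in self.sequences.items():
            hay = seq.replace("I", "L") if equate_il else seq
            if pep in hay:
                hits.append(acc)
        return hits


@dataclass(frozen=True)
class PeptideAssignment:
    peptide: str
    accession: str | None
    tier: str | None
    n_primary: int
    n_secondary: int


def _accession_from_header(header: str) -> str:
    """First token of the header; UniProt 'db|ACC|NAME' yields ACC."""
    token = header.split()[0]
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return token


def read_fasta_database(path: str | Path, tier: str = "primary") -> ProteinDatabase:
    """Load a FASTA protein database with standard UniProt-style headers."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(record.description or record.id)
        if acc in sequences:
            raise ValueError(f"duplicate accession {acc} in {tier} database")
        sequences[acc] = str(record.seq).upper()
    return ProteinDatabase(tier=tier, sequences=sequences)


def map_peptides_two_tier(
    peptides: list[str],
    primary_db: ProteinDatabase,
    secondary_db: ProteinDatabase | None = None,
    equate_il: bool = False,
) -> tuple[list[PeptideAssignment], dict[str, int]]:
    """Assign peptides to proteins by the two-tier uniqueness rule.

    Returns the per-peptide assignments and summary counts
    (assigned_primary, assigned_secondary, ambiguous, unmatched) that
    partition the peptide list exactly.
    """
    if not peptides:
        raise ValueError("no peptides to map")
    assignments = []
    summary = {
        "assigned_primary": 0,
        "assigned_secondary": 0,
        "ambiguous": 0,
        "unmatched": 0,
    }
    for pep in peptides:
        if not pep:
            raise ValueError("empty peptide sequence")
        hits1 = primary_db.matches(pep, equate_il)
        hits2: list[str] = []
        if len(hits1) == 1:
            assignments.append(PeptideAssignment(pep, hits1[0], "primary", 1, 0))
            summary["assigned_primary"] += 1
        elif len(hits1) > 1:
            assignments.append(PeptideAssignment(pep, None, None, len(hits1), 0))
            summary["ambiguous"] += 1
        else:
            if secondary_db is not None:
                hits2 = secondary_db.matches(pep, equate_il)
            if len(hits2) == 1:
                assignments.append(PeptideAssignment(pep, hits2[0], "secondary", 0, 1))
                summary["assigned_secondary"] += 1
            elif len(hits2) > 1:
                assignments.append(PeptideAssignment(pep, None, None, 0, len(hits2)))
                summary["ambiguous"] += 1
            else:
                assignments.append(PeptideAssignment(pep, None, None, 0, 0))
                summary["unmatched"] += 1
    return assignments, summary
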