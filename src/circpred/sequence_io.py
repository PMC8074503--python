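"""Reading, validating and writing protein sequence data.

Only the 20 canonical one-letter amino-acid codes are accepted.  Sequences
containing ambiguity or non-standard codes (B, J, O, U, X, Z) cannot be
encoded into the numeric feature space and are rejected or skipped at parse
time.  Input is uppercased and a single trailing ``*`` stop codon is stripped
before validation, matching the common proteome-FASTA dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: Default usable sequence-length range (residues) for training/prediction.
MIN_LENGTH: int = 39
MAX_LENGTH: int = 1000


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the canonical 20 residues."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated amino-acid sequence with its FASTA identity.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    the full header is retained as ``description``.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise InvalidSequenceError(
                f"record {self.id!r}: non-canonical residue(s) "
                f"{''.join(sorted(bad))!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _clean(raw: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    return seq


def read_fasta(
    path: str | Path,
    policy: Literal["reject", "skip"] = "reject",
) -> list[ProteinRecord]:
    """Parse a protein FASTA file into validated records, in file order.

    Parameters
    ----------
    path
        FASTA file (wrapped or unwrapped).
    policy
        ``"reject"``: raise :class:`InvalidSequenceError` at the first record
        with ambiguous residues (B, J, O, U, X, Z) or an empty sequence,
        naming the record and the offending character(s).
        ``"skip"``: drop such records, logging how many were skipped.
    """
    if policy not in ("reject", "skip"):
        raise ValueError(f"unknown policy {policy!r}")
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line
                break
    if not text_head:
        raise ValueError(f"{path}: empty FASTA file")
    if not text_head.startswith(">"):
        raise ValueError(f"{path}: malformed FASTA (sequence line before any header)")

    records: list[ProteinRecord] = []
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(
                ProteinRecord(
                    id=rec.id,
                    sequence=_clean(str(rec.seq)),
                    description=rec.description,
                )
            )
        except InvalidSequenceError:
            if policy == "reject":
                raise
            n_skipped += 1
    if n_skipped:
        logger.info("read_fasta(%s): skipped %d invalid record(s)", path, n_skipped)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapped)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def filter_by_length(
    records: Iterable[ProteinRecord],
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split records into (kept, dropped) by inclusive length bounds.

    Order is preserved and the two lists partition the input.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    kept, dropped = [], []
    for rec in records:
        (kept if min_len <= rec.length <= max_len else dropped).append(rec)
    return kept, dropped


def write_prediction_table(table, path: str | Path) -> None:
    """Write a prediction table (id, length, bin, probability, label, ...) as TSV."""
    table.to_csv(path, sep="\t", index=False)
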