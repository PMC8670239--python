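"""Reading, validating and cleaning protein sequences; feature-table I/O.

FASTA parsing is delegated to Biopython; this module adds the cleaning
policies (how non-standard residues such as B, J, O, U, X, Z are handled)
and the length guard (a sequence must contain at least one dipeptide).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO

from ddecnn.errors import (
    FastaFormatError,
    InvalidResidueError,
    SequenceTooShortError,
)

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.  This order
#: is the canonical ordering for all feature layouts in the package.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

CleanPolicy = Literal["strict", "skip_invalid"]


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: id, free-text description and a cleaned sequence.

    Invariants: non-empty id; sequence over the 20 standard uppercase
    amino-acid letters; length >= 2 so at least one dipeptide exists.
    """

    id: str
    sequence: str
    description: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if len(self.sequence) < 2:
            raise SequenceTooShortError(
                f"record {self.id!r}: cleaned sequence has length "
                f"{len(self.sequence)} < 2, no dipeptide exists"
            )
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)} "
                "remain after cleaning"
            )


def clean_sequence(raw: str, policy: CleanPolicy = "skip_invalid") -> str:
    """Normalize a raw sequence string to the 20-letter uppercase alphabet.

    Whitespace and stop marks ('*') are always stripped and letters
    uppercased.  Under ``strict``, any remaining non-standard character
    raises :class:`InvalidResidueError` with its 1-based position; under
    ``skip_invalid`` such characters (B, J, O, U, X, Z, gaps, ...) are
    removed with a logged warning.  A cleaned length below 2 raises
    :class:`SequenceTooShortError`.
    """
    if not raw:
        raise ValueError("empty sequence string")
    if policy not in ("strict", "skip_invalid"):
        raise ValueError(f"unknown cleaning policy {policy!r}")

    stripped = "".join(ch for ch in raw.upper() if not ch.isspace() and ch != "*")
    if policy == "strict":
        for pos, ch in enumerate(stripped, start=1):
            if ch not in _STANDARD_SET:
                raise InvalidResidueError(ch, pos)
        cleaned = stripped
    else:
        removed = [ch for ch in stripped if ch not in _STANDARD_SET]
        if removed:
            logger.warning(
                "removed %d non-standard residue(s) (%s)",
                len(removed), ",".join(sorted(set(removed))),
            )
        cleaned = "".join(ch for ch in stripped if ch in _STANDARD_SET)

    if len(cleaned) < 2:
        raise SequenceTooShortError(
            f"sequence has length {len(cleaned)} after cleaning; "
            "at least 2 residues are required"
        )
    return cleaned


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path, policy: CleanPolicy = "skip_invalid"
) -> list[ProteinRecord]:
    """Read a FASTA file (plain or gzip) into cleaned ProteinRecords.

    One record per '>' header, multi-line bodies concatenated, input order
    preserved.  Duplicate ids are allowed but logged; records are keyed by
    position.  Sequence data before any header is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    with _open_text(path) as fh:
        head = fh.read(1)
        while head and head.isspace():
            head = fh.read(1)
        if head and head != ">":
            raise FastaFormatError(
                f"{path}: sequence data before any '>' header"
            )

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                logger.warning("duplicate FASTA id %r (records keyed by position)", rec.id)
            seen.add(rec.id)
            description = rec.description[len(rec.id):].strip()
            records.append(
                ProteinRecord(
                    id=rec.id,
                    sequence=clean_sequence(str(rec.seq), policy),
                    description=description,
                )
            )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with open(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start:start + width] + "\n")


def write_feature_table(
    table: pd.DataFrame, path: str | Path, sep: str = "\t"
) -> None:
    """Write a feature table: first column ``id``, then 400 dipeptide columns."""
    table.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_feature_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited feature table written by :func:`write_feature_table`.

    With ``sep=None`` the delimiter is sniffed from the extension
    (.csv comma, otherwise tab).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)
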