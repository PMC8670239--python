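"""The DDE (Dipeptide Deviation from Expected mean) descriptor.

A protein of length ``l`` contains ``N = l - 1`` overlapping dipeptides out
of ``20 x 20 = 400`` possible types.  For each dipeptide ``i`` the descriptor
compares the observed composition

    Dc(i) = n_i / N

with the composition expected under independent codon usage,

    TM(i) = (C_1 / 61) * (C_2 / 61),

where ``C_k`` is the number of synonymous codons of the k-th residue of the
dipeptide and 61 is the number of sense codons in the standard genetic code.
The binomial variance of ``Dc(i)`` around ``TM(i)`` is

    TV(i) = TM(i) * (1 - TM(i)) / N,

and the feature is the standardized deviation

    DDE(i) = (Dc(i) - TM(i)) / sqrt(TV(i)).

The 400 values, ordered with the first residue varying slowest
(alphabetical one-letter order ACDEFGHIKLMNPQRSTVWY), form the feature
vector; reshaped row-major they give the 20x20 grid the convolutional
network consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ddecnn.errors import SequenceTooShortError
from ddecnn.sequence_io import ProteinRecord, STANDARD_AA

#: Canonical amino-acid order for all 400-dimensional layouts.
AA_ORDER: str = STANDARD_AA

#: Dipeptide names in canonical order: index 20*i + j is (aa_i, aa_j).
DIPEPTIDES: list[str] = [a + b for a in AA_ORDER for b in AA_ORDER]

_AA_INDEX = {aa: k for k, aa in enumerate(AA_ORDER)}

#: Synonymous-codon counts under the standard genetic code (61 sense codons).
_CODON_COUNTS: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}

Denominator = Literal["sqrt", "raw"]


@dataclass(frozen=True)
class CodonCountTable:
    """Synonymous-codon counts per amino acid; totals must equal 61."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(AA_ORDER):
            raise ValueError("codon table must cover exactly the 20 standard amino acids")
        if any(c not in (1, 2, 3, 4, 6) for c in self.counts.values()):
            raise ValueError("each degeneracy count must be one of {1,2,3,4,6}")
        if sum(self.counts.values()) != 61:
            raise ValueError("codon counts must sum to 61 sense codons")

    @property
    def cn(self) -> int:
        """Total number of sense codons (64 minus the three stops)."""
        return 61

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[aa] for aa in AA_ORDER], dtype=np.int64)


#: The standard genetic code's table, used everywhere by default.
STANDARD_CODON_TABLE = CodonCountTable(_CODON_COUNTS)


@dataclass(frozen=True)
class DDEVector:
    """The 400-dimensional DDE profile of one sequence."""

    values: np.ndarray
    n_dipeptides: int
    source_id: str = field(default="")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (400,):
            raise ValueError(f"DDE vector must have exactly 400 entries, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("DDE vector contains non-finite entries")
        object.__setattr__(self, "values", v)


def _residue_indices(sequence: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_AA_INDEX[ch] for ch in sequence), dtype=np.int64, count=len(sequence)
        )
    except KeyError as exc:  # pragma: no cover - guarded upstream by cleaning
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None


def dipeptide_counts(sequence: str) -> tuple[np.ndarray, int]:
    """Count the overlapping dipeptides of a cleaned sequence.

    Returns the 400-cell count vector in canonical order and
    ``N = len(sequence) - 1``; the counts sum to N.
    """
    if len(sequence) < 2:
        raise SequenceTooShortError(
            f"length {len(sequence)} sequence has no dipeptide"
        )
    idx = _residue_indices(sequence)
    flat = 20 * idx[:-1] + idx[1:]
    counts = np.bincount(flat, minlength=400).astype(np.int64)
    return counts, len(sequence) - 1


def dipeptide_composition(counts: np.ndarray, n: int) -> np.ndarray:
    """Dc(i) = n_i / N; the 400 compositions sum to one."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return np.asarray(counts, dtype=np.float64) / n


def theoretical_means(table: CodonCountTable = STANDARD_CODON_TABLE) -> np.ndarray:
    """TM for all 400 dipeptides, TM(ab) = (C_a/61)(C_b/61).

    Computed once in exact rational arithmetic and emitted as doubles; the
    values are sequence-independent and sum to exactly one.
    """
    fr = [Fraction(table.counts[aa], table.cn) for aa in AA_ORDER]
    return np.array([float(fa * fb) for fa in fr for fb in fr], dtype=np.float64)


def theoretical_variance(tm: float | np.ndarray, n: int) -> float | np.ndarray:
    """TV = TM(1 - TM)/N, the binomial variance of Dc around TM."""
    if n < 1:
        raise ValueError("N must be >= 1")
    tm = np.asarray(tm, dtype=np.float64)
    if np.any((tm <= 0) | (tm >= 1)):
        raise ValueError("TM values must lie strictly inside (0, 1)")
    out = tm * (1.0 - tm) / n
    return float(out) if out.ndim == 0 else out


def dde_vector(
    sequence: str,
    source_id: str = "",
    table: CodonCountTable = STANDARD_CODON_TABLE,
    denominator: Denominator = "sqrt",
) -> DDEVector:
    """Compute the full 400-dimensional DDE profile of one sequence.

    ``denominator="sqrt"`` (default) standardizes by the standard deviation
    sqrt(TV), giving a z-score per dipeptide; ``"raw"`` divides by the
    variance TV itself, the literal reading of the defining formula, kept
    for comparison.
    """
    counts, n = dipeptide_counts(sequence)
    dc = dipeptide_composition(counts, n)
    tm = theoretical_means(table)
    tv = theoretical_variance(tm, n)
    denom = np.sqrt(tv) if denominator == "sqrt" else tv
    return DDEVector(values=(dc - tm) / denom, n_dipeptides=n, source_id=source_id)


def to_grid(vec: DDEVector) -> np.ndarray:
    """Reshape the 400-vector into the 20x20 grid (row = first residue)."""
    return vec.values.reshape(20, 20)


def to_network_tensor(vec: DDEVector) -> np.ndarray:
    """Lay the grid out as the network input: 20 channels x height 1 x width 20.

    Channel c carries grid row c (the first residue of the dipeptide); the
    width axis is the second residue.  This layout reproduces the reference
    architecture's printed shapes and parameter counts (a 3x3 kernel over a
    1x20 extent with 20 input channels).
    """
    return to_grid(vec).reshape(20, 1, 20)


def featurize_records(
    records: Iterable[ProteinRecord],
    table: CodonCountTable = STANDARD_CODON_TABLE,
    denominator: Denominator = "sqrt",
    post_standardize: bool = False,
) -> pd.DataFrame:
    """DDE profiles of many records as a table: ``id`` plus 400 columns.

    ``post_standardize`` optionally z-scales each of the 400 columns across
    the dataset after DDE (zero-variance columns are left centred only).
    """
    records = list(records)
    rows = np.empty((len(records), 400), dtype=np.float64)
    for k, rec in enumerate(records):
        rows[k] = dde_vector(
            rec.sequence, rec.id, table=table, denominator=denominator
        ).values
    if post_standardize and len(records) > 1:
        mu = rows.mean(axis=0)
        sd = rows.std(axis=0)
        rows = (rows - mu) / np.where(sd > 0, sd, 1.0)
    out = pd.DataFrame(rows, columns=DIPEPTIDES)
    out.insert(0, "id", [rec.id for rec in records])
    return out


def table_to_tensors(table: pd.DataFrame) -> np.ndarray:
    """Stack a feature table's rows as network tensors, shape (n, 20, 1, 20)."""
    missing = [d for d in DIPEPTIDES if d not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks {len(missing)} dipeptide columns")
    values = table[DIPEPTIDES].to_numpy(dtype=np.float64)
    return values.reshape(-1, 20, 1, 20)
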