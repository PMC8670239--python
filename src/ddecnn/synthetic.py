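"""Synthetic two-class protein sequence benchmarks.

Real enzyme/non-enzyme collections are not redistributable here, so tests
and examples run on generated sequences.  Negatives are first-order Markov
chains with uniform residue emission; positives share the chain but the
transition probabilities into a fixed set of 20 motif dipeptides are
multiplied by an enrichment factor and renormalized.  Because the signal is
injected at the dipeptide-transition level, it lives exactly in the space
the DDE descriptor measures, and the enrichment factor is a clean dial on
class separability (1.0 makes the classes exchangeable).

Default sizes mirror the benchmark collection the pipeline emulates:
652 positives, 1,108 negatives, lengths 50-600, with a stratified
independent hold-out of 129 positives and 249 negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ddecnn.dde import AA_ORDER
from ddecnn.evaluation import independent_holdout_split, stratified_k_fold
from ddecnn.sequence_io import ProteinRecord, write_fasta

logger = logging.getLogger(__name__)

#: Fixed, versioned motif set: one enriched successor per first residue, so
#: every row of the positive-class transition matrix is perturbed once.
DEFAULT_MOTIF_DIPEPTIDES: tuple[str, ...] = (
    "AC", "CD", "DE", "EF", "FG", "GH", "HI", "IK", "KL", "LM",
    "MN", "NP", "PQ", "QR", "RS", "ST", "TV", "VW", "WY", "YA",
)

_AA_INDEX = {aa: k for k, aa in enumerate(AA_ORDER)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults are the package's standard benchmark."""

    n_pos: int = 652
    n_neg: int = 1108
    length_min: int = 50
    length_max: int = 600
    motif_dipeptides: tuple[str, ...] = DEFAULT_MOTIF_DIPEPTIDES
    enrichment: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one sequence")
        if not (2 <= self.length_min <= self.length_max):
            raise ValueError("need 2 <= length_min <= length_max")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        for d in self.motif_dipeptides:
            if len(d) != 2 or any(ch not in _AA_INDEX for ch in d):
                raise ValueError(f"invalid motif dipeptide {d!r}")
        object.__setattr__(self, "motif_dipeptides", tuple(self.motif_dipeptides))


def transition_matrix(spec: SyntheticSpec, positive: bool) -> np.ndarray:
    """Row-stochastic 20x20 residue transition matrix of one class."""
    w = np.ones((20, 20), dtype=np.float64)
    if positive:
        for d in spec.motif_dipeptides:
            w[_AA_INDEX[d[0]], _AA_INDEX[d[1]]] *= spec.enrichment
    return w / w.sum(axis=1, keepdims=True)


def _sample_sequence(length: int, cum: np.ndarray, rng: np.random.Generator) -> str:
    states = np.empty(length, dtype=np.int64)
    u = rng.random(length)
    states[0] = int(u[0] * 20)
    for t in range(1, length):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    return "".join(AA_ORDER[s] for s in states)


def generate_dataset(spec: SyntheticSpec) -> tuple[list[ProteinRecord], np.ndarray]:
    """Generate the labelled benchmark; deterministic under the spec's seed.

    Returns records (positives first, ids ``pos_0001`` ... / ``neg_0001``
    ...) and the binary label vector (1 = enzyme-like positive class).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    labels: list[int] = []
    for positive, n, prefix in ((True, spec.n_pos, "pos"), (False, spec.n_neg, "neg")):
        cum = np.cumsum(transition_matrix(spec, positive), axis=1)
        cum[:, -1] = 1.0  # guard against rounding in searchsorted
        lengths = rng.integers(spec.length_min, spec.length_max + 1, size=n)
        for k in range(n):
            records.append(
                ProteinRecord(
                    id=f"{prefix}_{k + 1:04d}",
                    sequence=_sample_sequence(int(lengths[k]), cum, rng),
                )
            )
            labels.append(1 if positive else 0)
    return records, np.asarray(labels, dtype=np.int64)


def write_benchmark(spec: SyntheticSpec, out_dir: str | Path, k: int = 5) -> dict[str, Path]:
    """Emit sequences.fasta, labels.tsv and splits.tsv into ``out_dir``.

    The split manifest assigns each id exactly one role: a stratified
    independent hold-out (129 positives and 249 negatives at the default
    sizes) or a cross-validation fold 0..k-1 within the training pool.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, labels = generate_dataset(spec)

    fasta = out_dir / "sequences.fasta"
    write_fasta(records, fasta)

    labels_path = out_dir / "labels.tsv"
    with open(labels_path, "wt") as fh:
        fh.write("id\tlabel\n")
        for rec, lab in zip(records, labels):
            fh.write(f"{rec.id}\t{lab}\n")

    hold = independent_holdout_split(labels, seed=spec.seed)
    train_idx = np.flatnonzero(~hold)
    folds = stratified_k_fold(labels[train_idx], k=k, seed=spec.seed)
    fold_of = dict(zip(train_idx.tolist(), folds.fold_index.tolist()))

    splits_path = out_dir / "splits.tsv"
    with open(splits_path, "wt") as fh:
        fh.write("id\trole\tfold\n")
        for i, rec in enumerate(records):
            if hold[i]:
                fh.write(f"{rec.id}\tindependent\t-\n")
            else:
                fh.write(f"{rec.id}\ttrain\t{fold_of[i]}\n")
    logger.info(
        "benchmark written: %d train / %d independent",
        int((~hold).sum()), int(hold.sum()),
    )
    return {"fasta": fasta, "labels": labels_path, "splits": splits_path}
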