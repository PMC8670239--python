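"""Exception hierarchy shared across the package."""


class DDECNNError(Exception):
    """Base class for package errors."""


class FastaFormatError(DDECNNError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class InvalidResidueError(DDECNNError):
    """A residue outside the 20-letter amino-acid alphabet under strict policy."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            f"(1-based); only the 20 standard amino-acid letters are allowed"
        )


class SequenceTooShortError(DDECNNError):
    """Sequence shorter than two residues: no dipeptide exists."""


class ConfigurationError(DDECNNError):
    """An architecture or training configuration that cannot be realized."""


class DivergenceError(DDECNNError):
    """Non-finite loss encountered during training."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


class IncompatibleModelError(DDECNNError):
    """Saved model artifacts inconsistent with each other or with the inputs."""


class LeakageError(DDECNNError):
    """Held-out evaluation attempted on sequences seen during training."""
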