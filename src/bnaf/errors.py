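"""Exception hierarchy for bnaf."""


class BnafError(Exception):
    """Base class for all bnaf errors."""


class InvalidStateError(BnafError):
    """A network state is malformed (wrong length, non-binary entries)."""


class NetworkParseError(BnafError):
    """A network file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SizeLimitError(BnafError):
    """Exhaustive state-space analysis refused: network exceeds the node cap."""


class MutationError(BnafError):
    """A mutation is inapplicable to the given network."""


class ExhaustionError(BnafError):
    """Not enough distinct mutants could be sampled within the retry budget."""


class IncomparableError(BnafError):
    """Two analyses/curves refer to networks of different size."""
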