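"""Exception hierarchy.

Every error class carries a process exit code so the CLI can map failure
modes to distinct statuses: parameter misuse, malformed wire data, failed
integrity checks (treated as erasures), and decode failure.
"""


class RatelessDnaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(RatelessDnaError, ValueError):
    """A function argument violates its precondition."""

    exit_code = 5


class OverflowFieldError(ParameterError):
    """A packet field value does not fit its configured byte width."""


class FormatError(RatelessDnaError):
    """Serialized data (packet bytes, FASTA, DNA string) is malformed."""

    exit_code = 2


class IllegalSymbolError(FormatError):
    """A DNA sequence contains a non-ACGT symbol."""


class IntegrityError(RatelessDnaError):
    """A checksum failed or error correction was exhausted.

    Packets raising this are treated as erased, mirroring the erasure
    channel: corruption is converted into loss.
    """

    exit_code = 3


class CorruptionError(RatelessDnaError):
    """A linear system is inconsistent: an undetected packet error slipped
    past the integrity layer (0 = nonzero right-hand side)."""

    exit_code = 3


class DecodeError(RatelessDnaError):
    """Not enough information to reconstruct the payload."""

    exit_code = 4


class ProgressTimeoutError(RatelessDnaError):
    """Strict-bound packet generation exhausted its seed budget."""

    exit_code = 6
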