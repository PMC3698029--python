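"""Exception hierarchy.

Validation errors (bad user input, bad configuration) are distinct from
runtime failures (corruption, transport, store) so the CLI can map them to
different exit codes.
"""


class SeqFarmError(Exception):
    """Base class for all package errors."""


class ValidationError(SeqFarmError, ValueError):
    """Invalid input or parameters, detected before any work is done."""


class FastaParseError(ValidationError):
    """Malformed FASTA input."""


class ConfigError(ValidationError):
    """Invalid run/store/farm configuration."""


class CorruptionError(SeqFarmError):
    """A checksum failed or a persisted artifact is truncated."""


class ProtocolError(SeqFarmError):
    """The master-worker dispatch protocol was violated."""


class TransportError(SeqFarmError):
    """A point-to-point message delivery failed."""


class StoreError(SeqFarmError):
    """Output-store lifecycle or backing-store failure."""


class OversizeRecordError(StoreError):
    """A single record payload exceeds the block capacity."""
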