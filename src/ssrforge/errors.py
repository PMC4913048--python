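"""Exception hierarchy shared across the pipeline."""


class SSRForgeError(Exception):
    """Base class for all package errors."""


class FastaParseError(SSRForgeError):
    """Malformed FASTA input (no header, sequence before header, empty file)."""


class ValidationError(SSRForgeError):
    """Input violates a documented invariant (duplicate id, bad coordinates)."""


class ConfigError(SSRForgeError):
    """Unknown or inconsistent configuration key/value."""


class DomainError(SSRForgeError):
    """Argument outside the operation's domain (e.g. non-ACGT character)."""


class FlankError(SSRForgeError):
    """Primer design requested for a locus without usable flanks."""


class GenerationError(SSRForgeError):
    """Synthetic-sequence generation could not satisfy its constraints."""
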