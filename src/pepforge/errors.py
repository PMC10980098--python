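"""Exception hierarchy shared across the package."""


class PepforgeError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(PepforgeError):
    """A PDB record could not be interpreted.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MissingChainError(PepforgeError):
    """A requested chain ID has no ATOM records in the input."""

    def __init__(self, chain_id: str):
        self.chain_id = chain_id
        super().__init__(f"no ATOM records found for chain {chain_id!r}")


class ConfigError(PepforgeError):
    """Invalid or inconsistent run configuration."""


class AdapterError(PepforgeError):
    """An external calculator adapter failed or returned garbage."""
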