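"""Exception hierarchy shared across crystkit modules."""


class CrystkitError(Exception):
    """Base class for all crystkit errors."""


class FastaParseError(CrystkitError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DuplicateIdError(CrystkitError):
    """Duplicate sequence identifiers where uniqueness is required."""

    def __init__(self, duplicates):
        self.duplicates = sorted(set(duplicates))
        super().__init__(f"duplicate ids: {', '.join(self.duplicates)}")


class ConfigurationError(CrystkitError):
    """Invalid user-supplied configuration (e.g. min_len > max_len)."""


class FixtureIntegrityError(CrystkitError):
    """Packaged data fixture failed its integrity checks."""


class OfflineError(CrystkitError):
    """Network access requested but not enabled."""


class StructureError(CrystkitError):
    """Problem reading or interpreting a molecular structure."""


class NewickParseError(CrystkitError):
    """Malformed Newick tree string."""
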