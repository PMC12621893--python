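"""Exception hierarchy shared across the package."""


class DelgemError(Exception):
    """Base class for all package errors."""


class ParseError(DelgemError, ValueError):
    """A SMILES string could not be parsed into a molecule."""


class ConfigError(DelgemError, ValueError):
    """An invalid parameter or configuration value."""


class DimensionError(DelgemError, ValueError):
    """Fingerprint width mismatch between operands."""


class DuplicateIdError(DelgemError, ValueError):
    """A catalog id appeared more than once while building an index."""


class AdapterError(DelgemError, RuntimeError):
    """An external scorer executable failed or produced malformed output."""


class CycleError(DelgemError, RuntimeError):
    """A pipeline cycle could not proceed (e.g. no valid samples)."""


class FitError(DelgemError, RuntimeError):
    """Dose-response curve fitting did not converge."""


class StatError(DelgemError, ValueError):
    """A statistical comparison is undefined for the given groups."""


class FixtureError(DelgemError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""
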