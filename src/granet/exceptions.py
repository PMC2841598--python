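"""Exception hierarchy shared across the package."""


class GranetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GranetError, ValueError):
    """Invalid user input (bad matrix, bad parameter, malformed file)."""


class ConfigurationError(GranetError, ValueError):
    """Inconsistent configuration (e.g. burn-in shorter than the maximum lag)."""


class DivergenceError(GranetError, RuntimeError):
    """A simulated system produced values beyond the runtime stability guard."""


class DegeneratePairError(GranetError, RuntimeError):
    """No usable lag order could be scored for a series pair."""
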