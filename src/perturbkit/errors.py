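"""Exception hierarchy for perturbkit.

All package errors derive from :class:`PerturbkitError` so callers can catch
one base class at pipeline boundaries.
"""


class PerturbkitError(Exception):
    """Base class for all perturbkit errors."""


class DegenerateInputError(PerturbkitError, ValueError):
    """Raised for empty or whitespace-only input text."""


class BudgetInfeasibleError(PerturbkitError):
    """The perturbation word budget exceeds the supply of eligible words.

    The corpus retention rule consumes this signal: records for which any
    grid condition is infeasible are dropped (and logged), never silently
    under-perturbed.
    """

    def __init__(self, required: int, available: int, detail: str = ""):
        self.required = required
        self.available = available
        msg = f"perturbation budget infeasible: need {required}, have {available}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ProviderError(PerturbkitError):
    """A homophone (or other external) provider failed; never a silent skip."""


class AdapterError(PerturbkitError):
    """A model adapter call failed (network, auth, malformed response)."""


class ConfigError(PerturbkitError, ValueError):
    """Invalid run configuration."""


class SchemaError(PerturbkitError, ValueError):
    """Malformed input record or results file."""
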