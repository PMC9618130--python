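"""Package-specific exceptions."""


class LossyCtxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LossyCtxError, ValueError):
    """A configuration value is invalid (names the offending field)."""


class VocabularyError(LossyCtxError, KeyError):
    """A token is not in the model vocabulary / lexicon."""


class StimulusDesignError(LossyCtxError, ValueError):
    """An item frame is incompatible with a requested condition."""


class BudgetExceededError(LossyCtxError, RuntimeError):
    """Exact enumeration would exceed the configured budget.

    Callers should fall back to importance sampling.
    """


class UndefinedBiasError(LossyCtxError, ValueError):
    """Embedding bias is undefined (zero occurrences, no smoothing)."""


class TrainingError(LossyCtxError, RuntimeError):
    """Policy optimization failed to converge; carries the training trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class InferenceError(LossyCtxError, RuntimeError):
    """Numerical failure during posterior inference (with diagnostics)."""
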