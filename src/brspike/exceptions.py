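"""Exception hierarchy for brspike."""


class BrspikeError(Exception):
    """Base class for all brspike errors."""


class ParameterError(BrspikeError, ValueError):
    """An operation parameter violates its contract (names the offending field)."""


class InputError(BrspikeError, ValueError):
    """Input data violates a structural precondition (grid, length, columns)."""


class ConfigError(BrspikeError, ValueError):
    """Experiment or pipeline configuration is invalid."""


class InsufficientEventsError(InputError):
    """Too few events/observations for the requested statistic."""


class DegenerateSignalError(InputError):
    """Signal has no usable structure (e.g. zero variance) for the operation."""


class NonIdentifiableError(BrspikeError, ValueError):
    """Model fit is not identifiable from the given data geometry."""


class FitConvergenceError(BrspikeError, RuntimeError):
    """Least-squares fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params
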