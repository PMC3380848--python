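"""Exception hierarchy for thermoflux."""


class ThermofluxError(Exception):
    """Base class for all thermoflux errors."""


class FormatError(ThermofluxError):
    """A file could not be parsed (bad cell, duplicate id, wrong shape)."""


class ValidationError(ThermofluxError):
    """Inputs are syntactically fine but violate a model invariant."""


class StallError(ThermofluxError):
    """A solver step cannot improve the selected constraint because the
    reaction column touches only clamped metabolites."""


class DivergenceError(ThermofluxError):
    """An iterate grew beyond the overflow guard; typically the descent
    step size is too large."""


class BudgetExceededError(ThermofluxError):
    """A combinatorial or iteration budget was exhausted before a decision
    could be reached.  Distinct from a definite 'not found'."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class LoopSearchError(ThermofluxError):
    """The solver failed to converge but no loop certificate could be
    located among the cycling constraints."""


class UnrepairableLoopError(ThermofluxError):
    """An infeasible loop was found whose members are all irreversible, so
    no direction flip can repair the assignment."""

    def __init__(self, message, certificate=None):
        super().__init__(message)
        self.certificate = certificate
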