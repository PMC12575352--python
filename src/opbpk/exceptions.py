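"""Exception hierarchy shared across the package."""


class OpbpkError(Exception):
    """Base class for all package errors."""


class DomainError(OpbpkError, ValueError):
    """A parameter is outside its physically meaningful domain."""


class UnsupportedSpeciesError(OpbpkError, KeyError):
    """Requested species has no reference physiology."""


class IncompleteKpSetError(OpbpkError, ValueError):
    """A partition-coefficient set does not cover every required tissue."""

    def __init__(self, missing, extra=()):
        self.missing = sorted(missing)
        self.extra = sorted(extra)
        msg = f"Kp set incomplete; missing tissues: {', '.join(self.missing)}"
        if self.extra:
            msg += f"; unknown tissues: {', '.join(self.extra)}"
        super().__init__(msg)


class SpeciesMismatchError(OpbpkError, ValueError):
    """Model components carry inconsistent species tags."""


class SolverError(OpbpkError, RuntimeError):
    """ODE integration failed; message carries a state snapshot."""


class EstimationError(OpbpkError, ValueError):
    """A profile does not support the requested estimate (e.g. too few points)."""


class UnitError(OpbpkError, ValueError):
    """Unsupported or inconsistent unit conversion."""
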