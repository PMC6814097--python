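"""Exception hierarchy shared across the package."""


class LtcmsmError(Exception):
    """Base class for all package-specific errors."""


class StructureError(LtcmsmError, ValueError):
    """Invalid state space or transition structure."""


class CovariateError(LtcmsmError, KeyError):
    """A covariate required by a model formula is missing or invalid."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class NumericRangeError(LtcmsmError, ArithmeticError):
    """A computation left the numerically safe range (e.g. exp overflow)."""


class AbsorbingStateError(LtcmsmError, ValueError):
    """An operation that needs a transient state was given an absorbing one."""


class BoundaryDiagnostic(LtcmsmError, RuntimeError):
    """A structurally allowed transition was never observed; the maximum of
    the likelihood lies on the boundary of the parameter space."""


class DataValidationError(LtcmsmError, ValueError):
    """One or more violations of the panel-data contract.

    Collects every violation found in a single pass so users can fix a file
    in one round trip.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        msg = "panel data failed validation:\n" + "\n".join(
            f"  - {p}" for p in self.problems
        )
        super().__init__(msg)
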