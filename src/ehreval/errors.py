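"""Exception hierarchy shared by all ehreval modules."""


class EhrevalError(Exception):
    """Base class for all package errors."""


class ValidationError(EhrevalError, ValueError):
    """Invalid input: bad field value, malformed file, mismatched grids.

    The message always names the offending field, cell or row so the error
    is actionable when it surfaces on the command line.
    """


class SampleSizeCapError(EhrevalError):
    """The sample-size search exceeded its cap without finding a feasible n."""

    def __init__(self, cap: int, p_expected: float, half_width: float):
        self.cap = cap
        self.p_expected = p_expected
        self.half_width = half_width
        super().__init__(
            f"sample size exceeds cap ({cap}) for expected proportion "
            f"{p_expected} at half-width {half_width}"
        )


class InfeasibleSamplingError(EhrevalError):
    """A sampling stratum cannot supply the requested number of documents."""

    def __init__(self, hospital_id: str, stratum: str, available: int, required: int):
        self.hospital_id = hospital_id
        self.stratum = stratum
        self.available = available
        self.required = required
        super().__init__(
            f"insufficient stratum: hospital {hospital_id!r}, stratum "
            f"{stratum!r}: {available} available, {required} required"
        )
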