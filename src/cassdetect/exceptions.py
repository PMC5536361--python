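"""Exception hierarchy for cassdetect."""


class CassError(ValueError):
    """Base class for all cassdetect errors."""


class InvalidParameterError(CassError):
    """A scalar parameter is outside its valid range."""


class InvalidInputError(CassError):
    """An input array is malformed (non-finite, wrong shape, too small)."""


class DegenerateKernelError(CassError):
    """A discretized kernel has no usable support."""


class DegenerateFitError(CassError):
    """A local weighted least-squares system is rank deficient."""


class InvalidSpecError(CassError):
    """A synthetic scene specification cannot be rendered."""
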