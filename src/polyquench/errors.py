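"""Exception hierarchy shared across polyquench modules."""


class PolyquenchError(Exception):
    """Base class for all package-specific errors."""


class FeasibilityError(PolyquenchError, ValueError):
    """A requested state or parameter set lies outside the model's feasible region."""


class SolverError(PolyquenchError, RuntimeError):
    """A numerical solve failed to converge or to bracket a root."""


class DataFormatError(PolyquenchError, ValueError):
    """An input file violates the expected plain-text format."""
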