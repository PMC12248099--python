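"""Exception types shared across fabgene modules."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable information
    (zero vector, all-constant matrix, empty held-out set)."""


class InsufficientReplicationError(ValueError):
    """Too few observations for the requested estimator or null
    distribution (e.g. fewer samples than projection dimensions)."""


class NumericalError(RuntimeError):
    """A linear-algebra step failed beyond what the fallbacks can absorb."""
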