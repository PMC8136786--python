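"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the physically meaningful domain."""


class DegenerateDistributionError(ValueError):
    """The requested distribution collapses to a delta function (r = 0)."""


class NumericsError(RuntimeError):
    """A numerical routine failed to meet its accuracy or stability contract."""
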