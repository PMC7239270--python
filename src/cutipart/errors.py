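"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Input data violate a structural precondition."""


class MissingTimeError(ValidationError):
    """A requested time point is not among a leaf's readings."""


class GapError(ValidationError):
    """A treatment group / hour combination required downstream is absent."""

    def __init__(self, group: str, hour: float):
        self.group = group
        self.hour = hour
        super().__init__(f"no data for group {group!r} at hour {hour}")


class SingularPartitionError(ValueError):
    """The treatment system cannot be inverted (k >= 1 or zero control rate)."""


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates had to be discarded."""


class PartitionWarning(UserWarning):
    """A partition estimate is outside its physically meaningful range."""
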