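"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file violates its format contract (bad column count,
    illegal character, out-of-range value ...). The message names the
    file and, where possible, the offending line."""


class ConfigError(ValueError):
    """The run configuration is inconsistent (missing threshold,
    missing mandatory input for the chosen run mode ...)."""


class DensityError(ValueError):
    """A density is undefined (zero-length denominator, zero motifs,
    or a degenerate chi-square table)."""


class FixtureError(RuntimeError):
    """The synthetic-fixture generator received an infeasible
    specification or failed to realise it."""


class FixtureValidationError(RuntimeError):
    """A generated fixture is inconsistent with its own truth table."""
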