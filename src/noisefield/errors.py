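"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config = 2, input = 3,
anything else = 1), so library code should raise the most specific
subclass that applies.
"""


class NoiseFieldError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NoiseFieldError, ValueError):
    """Invalid configuration (palette, stimulus geometry, run options)."""


class InputError(NoiseFieldError, ValueError):
    """Invalid data handed to an operation (files, counts, records)."""


class InvalidStateError(NoiseFieldError, ValueError):
    """A pseudorandom generator reached or was given an illegal state."""


class FixtureError(InputError):
    """A count fixture violates one of its internal consistency constraints."""


class GenerationError(NoiseFieldError, ValueError):
    """A synthetic record with the requested properties cannot exist."""


class NotApplicableError(NoiseFieldError, ValueError):
    """Agreement categorization requested for a field with no abnormal area."""
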