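"""Exception types shared across the package."""


class SoilviromeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SoilviromeError, ValueError):
    """A configuration value is invalid or inconsistent."""


class InputError(SoilviromeError, ValueError):
    """An input record violates the contract of an operation."""


class UndefinedMetricError(SoilviromeError, ValueError):
    """A summary statistic is undefined for the given input.

    Raised instead of silently returning 0 or NaN when a denominator is
    empty (e.g. the polyvalent fraction of a sample with no host-linked
    contigs, or TPM normalisation of an all-zero count vector).
    """
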