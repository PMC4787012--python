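"""Exception hierarchy shared across the package."""


class LinacPdmError(Exception):
    """Base class for all package errors."""


class ValidationError(LinacPdmError, ValueError):
    """Invalid value for a domain type (bad Sp fraction, bad segment, ...)."""


class FormatError(LinacPdmError, ValueError):
    """A log file does not conform to its dialect.

    Carries enough context (line number / key) to locate the defect.
    """

    def __init__(self, message: str, *, line: int | None = None, key: str | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if key is not None:
            loc.append(f"key {key!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.line = line
        self.key = key


class DegenerateTraceError(LinacPdmError, ValueError):
    """A positional trace (or reference) has zero variance; cross-correlation
    is undefined and the condition is flagged rather than silently zeroed."""


class ExtractionError(LinacPdmError, ValueError):
    """A daily sample could not be fully populated; lists the missing ids."""

    def __init__(self, message: str, missing: list[str] | None = None):
        if missing:
            message = f"{message}: {', '.join(sorted(missing))}"
        super().__init__(message)
        self.missing = tuple(missing or ())


class InsufficientBaselineError(LinacPdmError, ValueError):
    """Too few points to compute baseline statistics or rebaseline."""
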