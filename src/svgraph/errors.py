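"""Exception hierarchy.

All library errors derive from :class:`SvGraphError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class SvGraphError(Exception):
    """Base class for all svgraph errors."""


class CoordinateError(SvGraphError):
    """A position or interval falls outside the attached genome."""


class VcfParseError(SvGraphError):
    """A VCF record could not be interpreted as a structural variant."""


class GraphBuildError(SvGraphError):
    """Graph construction failed for a named event or contig."""


class GfaError(SvGraphError):
    """Malformed or structurally inconsistent GFA input."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class QueryError(SvGraphError):
    """A subgraph query could not be resolved."""


class ConfigError(SvGraphError):
    """A run configuration is missing or names a bad key."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key


class SimulationError(SvGraphError):
    """Invalid synthetic-data request (e.g. overlapping SV placements)."""
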