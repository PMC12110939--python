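"""Exception hierarchy.

All package-specific failures derive from :class:`CorneaSymError` so callers
can catch one type at the CLI boundary.
"""


class CorneaSymError(Exception):
    """Base class for all corneasym errors."""


class DimensionError(CorneaSymError):
    """A grid or table does not have the expected shape."""


class GridDialectError(CorneaSymError):
    """An elevation CSV contains cells that cannot be interpreted."""


class ManifestError(CorneaSymError):
    """A cohort manifest is malformed (columns, duplicate ids, dangling paths)."""


class ZoneExtentError(CorneaSymError):
    """A zone does not fit inside the grid, or is degenerate."""


class BoundsError(CorneaSymError):
    """Registration parameters exceed their configured bounds."""


class CoverageError(CorneaSymError):
    """Too few valid points inside the analysis zone."""


class DegenerateDataError(CorneaSymError):
    """Statistics requested on degenerate data (e.g. zero variance everywhere)."""
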