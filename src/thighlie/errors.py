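"""Exception hierarchy.

All data-dependent failures derive from :class:`ThighlieError` so the CLI can
map them to a stable exit code; programming errors (bad arguments) raise
plain ``ValueError``.
"""


class ThighlieError(Exception):
    """Base class for data-dependent processing errors."""


class ParseError(ThighlieError):
    """A raw-data file could not be parsed; carries the offending line."""

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        where = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{where}: {message}" if path else message)


class GapError(ThighlieError):
    """Sampling gaps beyond tolerance were found; lists the gap intervals."""

    def __init__(self, gaps, path=None):
        self.gaps = list(gaps)
        self.path = path
        desc = "; ".join(f"[{a} .. {b}]" for a, b in self.gaps[:5])
        more = "" if len(self.gaps) <= 5 else f" (+{len(self.gaps) - 5} more)"
        super().__init__(f"non-uniform sampling, gaps beyond tolerance: {desc}{more}")


class SyncError(ThighlieError):
    """Two-sensor time synchronisation failed or is low-confidence."""


class ReferenceError_(ThighlieError):
    """A reference interval is unusable for orientation correction."""


class AlignmentError(ThighlieError):
    """Two epoch series do not share a common grid."""
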