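"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors are handled by click
(exit 2), :class:`DataError` exits 3, :class:`FitError` exits 4.
"""


class CladekinError(Exception):
    """Base class for all package-specific errors."""


class DataError(CladekinError):
    """Invalid or inconsistent input data (bad FASTA, ragged alignment,
    unknown identifiers, malformed assay tables...)."""


class FitError(CladekinError):
    """A numerical fit could not produce a valid result (for example a
    non-positive Lineweaver-Burk intercept, matching an inactive enzyme)."""


class DegenerateDataError(CladekinError):
    """Data degenerate for the requested statistic (for example a paired
    t-test on zero-variance differences)."""
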