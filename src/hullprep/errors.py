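"""Exception hierarchy.

``ValidationError`` covers everything a user can cause (bad files, bad
coordinates, bad parameters); ``InternalConsistencyError`` covers states
that indicate a bug in the pipeline (labels out of range, flagged
endpoints).  The CLI maps them to exit codes 1 and 2 respectively.
"""


class HullprepError(Exception):
    """Base class for all package errors."""


class ValidationError(HullprepError):
    """Invalid user input: files, coordinates, or parameters."""


class InternalConsistencyError(HullprepError):
    """An internal invariant was violated; indicates a bug."""
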