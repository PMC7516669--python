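"""Exception types used across the package."""


class CadeeError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(CadeeError, ValueError):
    """A sample is too degenerate to carry entropy information.

    Raised e.g. when all values of a sample handed to the spacing
    estimator are identical, for which the plug-in answer would be
    negative infinity.
    """
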