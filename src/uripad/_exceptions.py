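"""Exception hierarchy shared by all uripad modules."""


class UriPadError(Exception):
    """Base class for all uripad errors."""


class InputError(UriPadError, ValueError):
    """A user-supplied input (file, argument, data table) is invalid."""


class AnalysisError(UriPadError, RuntimeError):
    """A computation could not be completed (non-convergence, degenerate data)."""
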