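"""Exception hierarchy."""


class HelixforgeError(Exception):
    """Base class for all helixforge errors."""


class FormatError(HelixforgeError):
    """A file could not be parsed or violates its format contract."""


class AlignmentError(HelixforgeError):
    """An alignment could not be built or is internally inconsistent."""


class ValidationError(HelixforgeError):
    """Input data violates a documented invariant."""


class SelectionError(HelixforgeError):
    """Template selection produced an empty or ill-defined result."""
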