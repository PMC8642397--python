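"""Exception types raised across the package."""


class PeakvoteError(Exception):
    """Base class for package-specific errors."""


class FormatError(PeakvoteError, ValueError):
    """A file is structurally unusable (missing columns, empty, bad labels)."""


class ParseError(PeakvoteError, ValueError):
    """A row or cell could not be parsed; the message names the offending row."""


class ModelVersionError(PeakvoteError):
    """A persisted model archive carries an incompatible format version."""


class AmbiguousPairError(PeakvoteError, ValueError):
    """More than one light (or heavy) peak group maps to one pairing key."""


class ZeroAreaError(PeakvoteError, ValueError):
    """A quantification candidate has zero total area on one side."""
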