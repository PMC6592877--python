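"""Exception hierarchy shared across the toolkit."""


class EEGBIDSError(Exception):
    """Base class for all toolkit errors."""


class GrammarError(EEGBIDSError):
    """A path does not parse under the BIDS entity filename grammar."""


class InvariantError(EEGBIDSError):
    """An in-memory object violates one of its declared invariants."""


class SchemaError(EEGBIDSError):
    """A TSV/JSON sidecar does not conform to its schema."""


class AmbiguityError(EEGBIDSError):
    """Two sidecars at the same level both apply to one data file."""


class FormatError(EEGBIDSError):
    """A binary/text data file is malformed or unsupported."""


class RangeError(EEGBIDSError):
    """A value falls outside the representable digital range."""


class PrecisionError(EEGBIDSError):
    """Requested data cannot be represented at the codec's precision."""


class CollisionError(EEGBIDSError):
    """Conversion target files already exist and overwrite was not requested."""


class UnknownCodeError(EEGBIDSError):
    """A violation code is not in the validator's rule catalog."""
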