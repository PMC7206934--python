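"""Exception hierarchy.

``CpeditError`` is the base; input/format problems raise subclasses so the
CLI can map them onto exit code 1 while genuine bugs (anything else)
surface as exit code 2.
"""


class CpeditError(Exception):
    """Base class for all package errors."""


class InputError(CpeditError):
    """Invalid user input (bad sequence, malformed name, bad config)."""


class FormatError(InputError):
    """A file or record violates its format contract."""


class LookupError_(InputError):
    """A requested record (gene, species, taxon) is absent."""


class ConsistencyError(InputError):
    """Two inputs that must agree (alignment vs gene, site vs gene) do not."""


class InfeasibleError(InputError):
    """The synthetic generator cannot satisfy the requested constraints."""
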