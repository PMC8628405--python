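"""Exception hierarchy shared across the package."""


class OpsinSitesError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(OpsinSitesError):
    """A residue string contains a character outside the amino-acid alphabet."""


class AlignmentError(OpsinSitesError):
    """An alignment operation received inputs violating its contract."""


class SchemeError(OpsinSitesError):
    """A reference scheme is malformed or does not match its reference sequence."""


class TreeError(OpsinSitesError):
    """A tree operation received inputs violating its contract."""


class SimulationError(OpsinSitesError):
    """A simulation config is malformed; the message names the offending field."""
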