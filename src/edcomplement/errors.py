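"""Exception hierarchy shared across the toolkit."""


class EdcomplementError(Exception):
    """Base class for all toolkit errors."""


class FormatError(EdcomplementError):
    """Input file could not be parsed."""


class UnsupportedElementError(EdcomplementError):
    """An atom's element has no density parameterization."""


class SelectionError(EdcomplementError):
    """A ligand selector matched no atoms, or the split is degenerate."""


class EmptyPoseError(EdcomplementError):
    """An operation requires at least one atom."""


class MembershipError(EdcomplementError):
    """Referenced atom does not belong to the pose."""


class NoOverlapError(EdcomplementError):
    """No grid point carries density from both molecules above threshold."""


class SingularFitError(EdcomplementError):
    """Regression abscissa is degenerate (too few points or no spread)."""


class IncompatiblePosesError(EdcomplementError):
    """Two poses do not share the same element multiset."""


class InsufficientReferencesError(EdcomplementError):
    """Envelope construction needs at least two reference fits."""
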