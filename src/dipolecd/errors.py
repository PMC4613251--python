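"""Exception hierarchy.

Grouped so the command-line layer can map error classes to distinct exit
codes: input/format problems, parameter problems, geometry problems, and
numerical failures.
"""


class DipoleCDError(Exception):
    """Base class for all package errors."""


# -- input / structure errors -------------------------------------------------

class FormatError(DipoleCDError):
    """A file could not be parsed in the expected format."""


class EmptyStructureError(DipoleCDError):
    """A structure file contained no usable ATOM records."""


class MissingAtomError(DipoleCDError):
    """A residue lacks backbone atoms required by the model."""


# -- parameter errors ---------------------------------------------------------

class ParameterError(DipoleCDError):
    """A parameter set failed validation (missing field or out of range)."""


# -- geometry errors ----------------------------------------------------------

class GeometryError(DipoleCDError):
    """Degenerate or unphysical geometry (collinear amide, close contact)."""


class ContactError(GeometryError):
    """Two polarizable points are closer than the allowed minimum separation."""


class RebuildFailureError(GeometryError):
    """More than half of the protein had to be dropped during a rebuild."""


# -- numerical errors ---------------------------------------------------------

class NumericalError(DipoleCDError):
    """Non-finite values or a failed linear-algebra step."""


class SingularBlockError(NumericalError):
    """The nondispersive block is singular or too ill-conditioned to reduce."""


class WindowError(DipoleCDError):
    """A comparison window contains no usable overlap between two spectra."""
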