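"""Exception hierarchy shared across the toolkit."""


class CasiteError(Exception):
    """Base class for all toolkit errors."""


class PDBParseError(CasiteError):
    """A PDB record could not be parsed; the message names the line number."""


class MissingAtomsError(CasiteError):
    """A residue lacks atoms required for the requested selection."""


class TemplateFormatError(CasiteError):
    """A template file violates the template text format."""


class EnsembleError(CasiteError):
    """A site ensemble cannot be assembled or clustered."""


class DegenerateGeometryWarning(UserWarning):
    """Superposition input is (near-)collinear; the rotation is not unique."""
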