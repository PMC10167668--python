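"""Exception hierarchy for flexbuild."""


class FlexbuildError(Exception):
    """Base class for all flexbuild errors."""


class UnsupportedResidueError(FlexbuildError):
    """Residue type has no chi definitions / library entries."""


class IncompleteSideChainError(FlexbuildError):
    """A residue is missing an atom needed to define or rotate a dihedral."""

    def __init__(self, residue_id, atom_name):
        self.residue_id = residue_id
        self.atom_name = atom_name
        super().__init__(f"incomplete side chain: residue {residue_id} "
                         f"is missing atom {atom_name!r}")


class LibraryParseError(FlexbuildError):
    """The rotamer-library table could not be parsed."""


class MapFormatError(FlexbuildError):
    """A density-map file is truncated, invalid or lacks cell parameters."""


class FlatMapError(FlexbuildError):
    """Sigma scaling is impossible: the map has zero variance."""


class ParameterError(FlexbuildError):
    """A user-supplied parameter is out of its valid range."""


class BuildError(FlexbuildError):
    """Multi-conformer building cannot proceed (e.g. altloc exhaustion)."""
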