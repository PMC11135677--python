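"""Exception types shared across the pipeline."""


class UrbantolError(Exception):
    """Base class for pipeline errors."""


class ParameterError(UrbantolError, ValueError):
    """An argument is outside its documented domain."""


class GridMismatchError(UrbantolError):
    """Two rasters or grids that must share a lattice do not."""


class ExtentError(UrbantolError):
    """A source layer does not overlap the target grid."""


class MetadataError(UrbantolError):
    """Required spatial metadata (e.g. a CRS) is missing or incompatible."""


class DegenerateLayerError(UrbantolError):
    """A PCA input layer is constant over the included cells."""


class CurationGapError(UrbantolError):
    """Taxa present in the records are missing from the curation table."""

    def __init__(self, names, message="taxa missing from curation table"):
        self.names = sorted(names)
        super().__init__(f"{message}: {', '.join(self.names)}")


class DegenerateDesignError(UrbantolError):
    """A statistical design has too few levels or replicates."""
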