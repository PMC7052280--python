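"""Exception hierarchy shared across the pipeline stages."""


class ThermofieldError(Exception):
    """Base class for all package errors."""


class DimensionError(ThermofieldError):
    """Incompatible shapes, non-tiling blocks, or non-positive sizes."""


class ConstraintError(ThermofieldError):
    """A randomization constraint could not be satisfied within the retry budget."""


class LayoutError(ThermofieldError):
    """Invalid virtual-grid layout (overlapping or out-of-range replicate spans)."""


class ParameterError(ThermofieldError):
    """A numeric parameter is outside its valid domain."""


class GeometryError(ThermofieldError):
    """Invalid viewing/imaging geometry (e.g. zenith >= 90 deg, camera below ground)."""


class InputError(ThermofieldError):
    """Structurally invalid input data (empty lists, mismatched lengths)."""


class FitError(ThermofieldError):
    """A least-squares or mixed-model fit could not be computed."""


class EstimabilityError(FitError):
    """Confounded design: an effect is not estimable."""


class ModeError(ThermofieldError):
    """Operation called on a fit of the wrong genotype mode."""


class DegeneratePolygonError(ThermofieldError):
    """An inward buffer consumed the polygon entirely."""


class ValidationError(ThermofieldError):
    """Real-input dataset failed schema validation."""

    def __init__(self, defects):
        self.defects = list(defects)
        super().__init__("; ".join(self.defects))
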