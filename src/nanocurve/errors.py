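"""Exception hierarchy for nanocurve."""


class NanocurveError(Exception):
    """Base class for all nanocurve failures."""


class RenderError(NanocurveError):
    """Synthetic field cannot be rendered with the given parameters."""


class LatticeError(NanocurveError):
    """Periodic lattice detection or tiling failed."""


class NotABarError(NanocurveError):
    """Averaged footprint is not elongated enough to derive bar ROIs."""


class DriftError(NanocurveError):
    """Frame-to-frame drift exceeds the allowed tolerance."""


class DegenerateHistogramError(NanocurveError):
    """Image histogram has no spread; auto-thresholding is undefined."""


class NoAdhesionsError(NanocurveError):
    """Auto-thresholding produced an empty adhesion mask."""


class NoCellsError(NanocurveError):
    """3D segmentation found no region above the volume filter."""


class ConfigError(NanocurveError):
    """Run configuration is invalid or incomplete."""
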