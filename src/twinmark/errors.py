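"""Exception and warning types shared across the package."""


class TwinmarkError(Exception):
    """Base class for all package-specific errors."""


# -- landmarks / regions ------------------------------------------------------

class MalformedLandmarkFile(TwinmarkError):
    """Landmark file does not contain 468 uniquely-indexed points."""


class DegeneratePolygon(TwinmarkError):
    """Region points are collinear or otherwise do not enclose an area."""


class NoFaceFound(TwinmarkError):
    """The detection backend found no face in the input."""


class BackendUnavailable(TwinmarkError):
    """A requested detector/descriptor backend is not installed or registered."""


# -- keypoints ----------------------------------------------------------------

class EmptyCrop(TwinmarkError):
    """Face box has zero area after clamping."""


class UnknownPairId(TwinmarkError):
    """Synthetic replay backend has no record of the requested pair."""


class MalformedBundle(TwinmarkError):
    """Keypoint/descriptor bundle file cannot be parsed or is inconsistent."""


# -- matching -----------------------------------------------------------------

class MetricMismatch(TwinmarkError):
    """Descriptor sets to be matched use different kinds or metrics."""


class InsufficientNeighbors(TwinmarkError):
    """Lowe ratio filter requires two neighbors but a candidate list has one."""


class DuplicateQueryIndex(TwinmarkError):
    """A query keypoint index appears more than once in the good-match list."""


# -- features -----------------------------------------------------------------

class DuplicateKind(TwinmarkError):
    """The same descriptor kind appears twice in a fusion request."""


class SchemaMismatch(TwinmarkError):
    """Feature vectors with different schemas cannot be fused."""


# -- dataset / classification -------------------------------------------------

class EmptyManifest(TwinmarkError):
    """Pair manifest contains no rows."""


class TooFewRows(TwinmarkError):
    """Not enough rows per class for the requested split."""


class SingleClassTraining(TwinmarkError):
    """Training data contains a single class."""


class InfeasibleSpec(TwinmarkError):
    """Synthetic cohort spec demands more planted points than the budget allows."""


class ConfigInvalid(TwinmarkError):
    """Run configuration failed validation."""


# -- statistics ---------------------------------------------------------------

class TooFewValues(TwinmarkError):
    """Fewer than two values per class for a summary statistic."""


class ZeroVarianceBothGroups(TwinmarkError):
    """Welch's t-test is undefined when both groups are constant."""


class UndefinedMetricWarning(UserWarning):
    """A classification metric has a zero denominator and is reported as NaN."""


class ZeroDenominatorWarning(UserWarning):
    """A ratio feature had a zero denominator and was defined as 0."""
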