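"""Exception hierarchy shared by all pipeline stages."""


class OncopanelError(Exception):
    """Base class for all toolkit errors."""


class FormatError(OncopanelError):
    """Malformed input file: bad column, value, or record structure."""


class ParameterError(OncopanelError):
    """Invalid parameter or configuration value."""


class EvidenceError(OncopanelError):
    """Insufficient read evidence to carry out a computation."""


class ModelError(OncopanelError):
    """Classifier model inconsistent with the supplied features."""


class TrainingError(OncopanelError):
    """Training data cannot support a fit (e.g. a single class)."""


class PlacementError(OncopanelError):
    """A breakpoint cannot be placed on the given transcript."""


class ProductError(OncopanelError):
    """No chimeric coding product can be constructed."""


class MetricError(OncopanelError):
    """A validation metric is undefined for the given inputs."""
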