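"""Exception hierarchy shared across the pipeline stages."""


class CortexDtiError(Exception):
    """Base class for all package-specific errors."""


class ContractError(CortexDtiError):
    """An input violated a documented precondition."""


class ParameterError(CortexDtiError):
    """A configuration parameter is outside its valid range."""


class FormatError(CortexDtiError):
    """A file could not be parsed in the expected dialect."""


class UnfittableDesignError(CortexDtiError):
    """Too few usable volumes to fit the diffusion tensor model."""


class MissingBaselineError(CortexDtiError):
    """No non-diffusion-weighted (b~0) volume in the acquisition."""


class TopologyError(CortexDtiError):
    """The grey-matter ribbon does not connect both boundaries."""


class DesignError(CortexDtiError):
    """A statistical design matrix is rank deficient or otherwise invalid."""


class VarianceError(CortexDtiError):
    """A group is too small to estimate a variance."""


class StratificationError(CortexDtiError):
    """A class has fewer members than the number of CV folds."""


class UnknownModelError(CortexDtiError):
    """Requested classifier is not in the model zoo."""


class UnseenClassError(CortexDtiError):
    """Test data contains a class absent from the training data."""
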