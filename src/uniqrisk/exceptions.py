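"""Exception hierarchy for uniqrisk."""


class UniqriskError(Exception):
    """Base class for all uniqrisk errors."""


class ConfigurationError(UniqriskError):
    """A configuration value (column name, rule, config key) is invalid."""


class InputError(UniqriskError):
    """Input data violates a precondition (empty table, inconsistent totals)."""


class ContainmentError(UniqriskError):
    """The sample is not contained in the population (linkage impossible)."""


class ParameterError(UniqriskError):
    """A numeric parameter is outside its admissible range."""


class GeneralizationError(UniqriskError):
    """A value could not be parsed under a generalization rule."""
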