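"""Exception hierarchy for the ivmr package."""


class IVMRError(Exception):
    """Base class for all ivmr errors."""


class ConfigurationError(IVMRError):
    """A required column, parameter, or input for the chosen method is missing."""


class ValidationError(IVMRError):
    """Input data violate a contract (duplicate rsids, empty set, bad threshold...)."""


class ParseError(IVMRError):
    """A value in an input table could not be parsed."""


class SingularDesignError(IVMRError):
    """The regression design matrix is singular or ill-conditioned."""
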