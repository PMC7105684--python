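"""Exception hierarchy shared across the package."""


class GsblupError(Exception):
    """Base class for all package errors."""


class ParseError(GsblupError):
    """A genotype or phenotype file could not be parsed."""


class ValidationError(GsblupError):
    """Input violates a structural invariant (duplicate IDs, bad grid, ...)."""


class DepthUnavailableError(GsblupError):
    """Read-depth filtering requested but the source carries no depth."""


class NonBiallelicError(GsblupError):
    """A non-biallelic marker reached a step that requires biallelic SNPs."""


class ConvergenceWarning(UserWarning):
    """A REML fit stopped before meeting its tolerance."""


class EligibilityError(GsblupError):
    """A training design fails a minimum-size rule (genets or observations)."""
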