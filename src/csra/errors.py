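"""Exception hierarchy for the CSRA pipeline."""


class CsraError(Exception):
    """Base class for all pipeline errors."""


class DegenerateControlError(CsraError):
    """Vehicle-control signal does not exceed the blank signal."""


class IncompleteLadderError(CsraError):
    """A dose plate or inhibition profile does not cover the six TDC fractions."""


class InvalidScoreError(CsraError):
    """A sensitivity index is non-finite."""


class FormatError(CsraError):
    """A required column or field is missing from an input file."""


class EmptyPanelError(CsraError):
    """A gene-panel file contains no symbols."""


class UnknownSpecimenError(CsraError):
    """A variant refers to a specimen absent from the cohort."""


class DomainError(CsraError):
    """Invalid hypergeometric margins or contingency counts."""


class ConfigError(CsraError):
    """An invalid simulation or reporting configuration value."""


class JoinError(CsraError):
    """Input tables do not share a specimen universe."""
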