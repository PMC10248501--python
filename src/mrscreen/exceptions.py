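"""Exception hierarchy for the mrscreen pipeline."""


class MRScreenError(Exception):
    """Base class for all mrscreen errors."""


class ConfigurationError(MRScreenError):
    """A column map, threshold set, or simulation config is invalid."""


class InputError(MRScreenError):
    """An input table or record violates a precondition."""


class EmptyInputError(InputError):
    """A parsed table yielded zero valid records."""


class DomainError(MRScreenError, ValueError):
    """A numeric argument lies outside the domain of a formula."""


class InsufficientInstrumentsError(MRScreenError):
    """Fewer instruments than the method's minimum were supplied."""


class DegenerateInstrumentError(MRScreenError):
    """An instrument with zero exposure effect cannot yield a Wald ratio."""


class CollinearityError(MRScreenError):
    """The exposure effects carry no variance; the Egger slope is unidentified."""
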