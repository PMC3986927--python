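"""Exception hierarchy for phenoplate."""


class PhenoplateError(Exception):
    """Base class for all phenoplate errors."""


class SchemaError(PhenoplateError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(PhenoplateError):
    """A record violates an invariant; the message names the offending record."""
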