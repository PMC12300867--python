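"""Exception types shared across the package."""


class DietMarkovError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DietMarkovError):
    """A parameter table is missing a required column or has a bad layout."""


class DataError(DietMarkovError):
    """A parameter table is structurally valid but its content is wrong
    (duplicate strata, invariant violations detected at load time)."""


class ParseError(DietMarkovError):
    """A cell that should be numeric could not be parsed."""


class ModelError(DietMarkovError):
    """A model was parameterized outside its valid domain (negative
    probabilities, negative intake deltas, zero prevalent population...)."""
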