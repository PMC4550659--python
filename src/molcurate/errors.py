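"""Exception hierarchy for the curation toolkit.

Corpus-scale curation is annotate-and-flag: most questionable states
(conflicting charge dialects, implausible charges, InChI mismatches) are
recorded as values, not raised. Exceptions are reserved for inputs the
pipeline genuinely cannot process.
"""


class MolcurateError(Exception):
    """Base class for all toolkit errors."""


class CMLParseError(MolcurateError):
    """The document is not well-formed XML or not a recognizable CML molecule."""


class CMLValidationError(MolcurateError):
    """A record violates an invariant (bad element symbol, out-of-range bond index...)."""


class GeometryError(MolcurateError):
    """Coordinates are missing, non-finite, coincident or otherwise unusable."""


class InChIError(MolcurateError):
    """The reference InChI implementation failed; carries its diagnostics."""


class MopacParseError(MolcurateError):
    """Optimizer output text could not be interpreted."""


class ConfigurationError(MolcurateError):
    """A required external resource (schema, command, radius table) is unavailable."""


class InfeasibleSpecError(MolcurateError):
    """A synthetic-corpus injection specification asks for more than n_entries allows."""


class SearchPayloadError(MolcurateError):
    """A search-API response payload could not be parsed."""
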