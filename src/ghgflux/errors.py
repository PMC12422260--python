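"""Exception hierarchy.

``GHGFluxError`` is the common base so callers can catch everything the
package raises with one clause; the CLI maps input-side errors to exit
code 1 and anything else to 2.
"""


class GHGFluxError(Exception):
    """Base class for all package errors."""


class DomainError(GHGFluxError, ValueError):
    """A physical quantity is outside its valid range; names the field."""


class ConfigurationError(GHGFluxError, ValueError):
    """Invalid or inconsistent run configuration."""


class RegistryLookupError(GHGFluxError, KeyError):
    """Unknown k600 parameterization code."""


class SchemaError(GHGFluxError, ValueError):
    """A tabular input is missing mandatory columns or is malformed."""


class AggregationError(GHGFluxError, ValueError):
    """Campaign aggregation requested on an empty or mixed-species set."""


class BudgetError(GHGFluxError, ValueError):
    """Catchment budget inputs are incomplete."""


class AttributionError(GHGFluxError, ValueError):
    """A station cannot be mapped to a source class."""
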