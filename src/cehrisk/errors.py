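"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors are handled by click
(exit 2), :class:`CohortValidationError`/:class:`CatalogError`/
:class:`ConfigurationError` exit 3, :class:`DegenerateTableError` exits 4.
"""


class CehriskError(Exception):
    """Base class for all package errors."""


class CatalogError(CehriskError):
    """Malformed or inconsistent haplotype-group catalog."""


class CohortValidationError(CehriskError):
    """A cohort table violates the TSV contract (codes, header, ids)."""


class ConfigurationError(CehriskError):
    """A simulation or analysis configuration is invalid."""


class DegenerateTableError(CehriskError):
    """A contingency table cannot support the requested statistic
    (zero cell with correction off, empty reference stratum, ...)."""


class ResourceError(CehriskError):
    """A simulation request is infeasible at the configured rates."""
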