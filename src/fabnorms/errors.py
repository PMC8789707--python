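"""Exception hierarchy for the norming pipeline."""


class FabNormsError(Exception):
    """Base class for all package errors."""


class SchemaError(FabNormsError):
    """A required column is missing or a file cannot be parsed."""


class CohortValidationError(FabNormsError):
    """One or more rows violate record invariants.

    Carries row-indexed diagnostics in ``problems``: a list of
    ``(row_index, field, message)`` tuples.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = [f"  row {r}: {f}: {m}" for r, f, m in self.problems[:20]]
        more = len(self.problems) - len(lines)
        if more > 0:
            lines.append(f"  ... and {more} more")
        super().__init__("invalid cohort rows:\n" + "\n".join(lines))


class ConfigError(FabNormsError):
    """A configuration value is outside its valid domain."""


class TransformDomainError(FabNormsError):
    """A predictor value lies outside the domain of its transform."""


class SingularFitError(FabNormsError):
    """The regression design matrix is singular or degenerate."""


class DegenerateDataError(FabNormsError):
    """Input data cannot support the requested statistic (n too small,
    zero variance, single group, ...)."""


class NormsUnderivableError(FabNormsError):
    """No valid outer tolerance rank exists at this sample size."""


class IntegrityError(FabNormsError):
    """Shipped norm constants fail their checksum."""
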