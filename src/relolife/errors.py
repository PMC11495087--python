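"""Exception hierarchy.

Validation failures (malformed tables, out-of-range parameters) raise
:class:`ValidationError`; missing or unresolvable external resources raise
:class:`ResourceError`.  The CLI maps these to exit codes 2 and 3.
"""


class RelolifeError(Exception):
    """Base class for all package errors."""


class ValidationError(RelolifeError, ValueError):
    """Input data or configuration violates a documented invariant."""


class ResourceError(RelolifeError):
    """A referenced resource (file, table, curve) is missing or unusable."""


class CityLookupError(RelolifeError, KeyError):
    """A city id is absent from the city-year concentration table."""

    def __init__(self, city_id):
        super().__init__(city_id)
        self.city_id = city_id

    def __str__(self) -> str:  # KeyError quotes its arg; we want a sentence
        return f"city {self.city_id!r} not present in the city-year table"


class CoverageGapError(ValidationError):
    """Life-years exist for which no exposure value can be assigned."""

    def __init__(self, years):
        self.years = sorted(years)
        super().__init__(
            f"no exposure coverage for calendar years: {self.years}"
        )
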