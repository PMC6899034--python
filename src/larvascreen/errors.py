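"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`LarvaScreenError` so CLI entry
points can catch one type and report the offending stage and records.
"""


class LarvaScreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(LarvaScreenError):
    """Invalid campaign or pipeline configuration."""


class StatsError(LarvaScreenError):
    """Too few values / undefined statistic (e.g. Tukey fences on n < 4)."""


class DegeneratePlateError(StatsError):
    """Negative-control spread is zero; Z-scores undefined for the plate."""


class DataIntegrityError(LarvaScreenError):
    """Layout and measurement tables disagree (missing wells, conflicts)."""


class GenerationError(LarvaScreenError):
    """Synthetic rendering failed (e.g. infeasible non-overlap packing)."""


class FitError(LarvaScreenError):
    """Dose-response fitting input error (too few doses, bad params)."""


class DomainError(LarvaScreenError):
    """Requested quantity outside the valid domain of a fitted curve."""


class CascadeError(LarvaScreenError):
    """Invalid validation-cascade records (unknown paradigm, conflicts)."""
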