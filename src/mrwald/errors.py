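"""Exception hierarchy for mrwald.

All package-specific failures derive from :class:`MRWaldError` so callers can
catch one base class; the subclasses distinguish bad configuration, bad input
data, illegal operation order, and mathematically undefined estimates.
"""


class MRWaldError(Exception):
    """Base class for all mrwald errors."""


class ConfigurationError(MRWaldError):
    """A configuration problem, e.g. a required column missing after mapping."""


class InputError(MRWaldError):
    """Invalid input data, e.g. zero valid rows or duplicated variant ids."""


class StateError(MRWaldError):
    """An operation applied in an illegal state, e.g. rescaling twice."""


class UndefinedRatioError(MRWaldError):
    """Wald ratio requested for an instrument with zero exposure effect."""

    def __init__(self, rsid: str):
        self.rsid = rsid
        super().__init__(
            f"Wald ratio undefined for {rsid}: exposure beta is exactly zero"
        )
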