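"""Exception hierarchy for sliex."""


class SliexError(Exception):
    """Base class for all sliex errors."""


class InvalidMeasurementError(SliexError, ValueError):
    """A lipid concentration is non-positive, non-finite or otherwise unusable."""


class DomainError(SliexError, ValueError):
    """An unknown marker, unit or category was supplied."""


class UnitMismatchError(SliexError, ValueError):
    """Pre and post panels were measured in different units."""


class EmptyPanelError(SliexError, ValueError):
    """No marker is present in both the pre and post panel."""


class InsufficientDataError(SliexError, ValueError):
    """Too few observations for the requested statistic."""


class ShapeError(SliexError, ValueError):
    """Rating vectors or matrices have incompatible shapes."""


class DegenerateVarianceError(SliexError, ValueError):
    """No between-item variance: the intraclass correlation is undefined."""


class ConfigError(SliexError, ValueError):
    """An invalid simulation configuration."""


class NoValidRowsError(SliexError, ValueError):
    """An input file yielded zero parseable records."""
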