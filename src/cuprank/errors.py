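"""Exception and warning types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A study design, group-parameter table or run config is inconsistent."""


class DegenerateHistogramError(ValueError):
    """All histogram mass sits in a single bin; no two-class split exists."""


class NoRankableAnimalsError(ValueError):
    """Every animal was excluded; the rank composite is undefined."""


class ClassOverlapWarning(UserWarning):
    """Foreground/background intensity laws overlap enough to blur the two-class structure."""


class BlobOverlapWarning(UserWarning):
    """Expected spheroid overlap is high enough that component counting is ill-posed."""


class EmptyFieldWarning(UserWarning):
    """A spheroid field produced a degenerate histogram; density reported as 0."""


class SmallSampleWarning(UserWarning):
    """Sample too small (or constant) for a normality test; nonparametric route used."""
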