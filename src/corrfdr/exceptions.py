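"""Exception hierarchy for corrfdr."""


class CorrFdrError(Exception):
    """Base class for all corrfdr errors."""


class InvalidArgumentError(CorrFdrError, ValueError):
    """An argument violates a precondition (range, type, shape)."""


class ConfigurationError(CorrFdrError, ValueError):
    """A procedure was requested without the inputs it needs."""


class DegenerateFeatureError(CorrFdrError, ValueError):
    """A feature has zero pooled variance and cannot be tested or correlated."""

    def __init__(self, feature_id, message=None):
        self.feature_id = feature_id
        super().__init__(
            message or f"feature {feature_id!r} has zero variance; "
            "remove or filter constant features before screening"
        )
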