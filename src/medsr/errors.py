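"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid model or data configuration."""


class ContractError(ValueError):
    """An operation was called with arguments violating its contract
    (shape mismatch, misaligned pair, wrong channel count, ...)."""


class CalibrationError(RuntimeError):
    """No architecture within the search bounds meets a parameter budget."""
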