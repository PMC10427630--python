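"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A run or simulation configuration is internally inconsistent."""


class FormatError(ValueError):
    """An on-disk file does not conform to the expected dialect."""


class UnidentifiableModelWarning(UserWarning):
    """The fitted deconvolution model carries no usable cell-type signal."""
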