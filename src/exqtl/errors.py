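"""Exception hierarchy shared across the pipeline."""


class ExqtlError(Exception):
    """Base class for all package errors."""


class ConfigError(ExqtlError):
    """Invalid simulation or run configuration."""


class InputError(ExqtlError):
    """Malformed or inconsistent user-supplied data."""


class SingularDesignError(InputError):
    """Rank-deficient regression design; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class DependencyError(ExqtlError):
    """A pipeline stage was requested before the stage it depends on."""
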