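"""Exception hierarchy shared across the pipeline stages."""


class HerdmassError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HerdmassError):
    """Invalid generator/pipeline configuration (empty archetype list, missing truths, ...)."""


class UnmappableBreedError(HerdmassError):
    """A breed code could not be resolved to a category, even after cross-stripping."""

    def __init__(self, code: str):
        self.code = code
        super().__init__(f"breed code {code!r} not in breed map (after cross-suffix stripping)")


class InsufficientStratumError(HerdmassError):
    """A sampling stratum holds fewer records than requested."""

    def __init__(self, stratum: str, available: int, requested: int):
        self.stratum = stratum
        super().__init__(
            f"animal class {stratum!r} has {available} records, "
            f"{requested} requested for the stratified sample"
        )


class SingularDesignError(HerdmassError):
    """The regression design matrix is rank-deficient."""


class NonConvergenceError(HerdmassError):
    """Iterative break-point estimation failed and fallback was disabled."""


class SchemaError(HerdmassError):
    """A delimited table does not match the expected column schema."""

    def __init__(self, missing, path=None):
        self.missing = list(missing)
        loc = f" in {path}" if path else ""
        super().__init__(f"missing required columns{loc}: {', '.join(self.missing)}")
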