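"""Exception hierarchy for nihba."""


class NihbaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NihbaError):
    """A model file could not be parsed, or violates a structural invariant."""


class ConfigurationError(NihbaError):
    """The run configuration is inconsistent (e.g. no objective reaction)."""


class InfeasibleModelError(NihbaError):
    """A required LP (wild-type growth, TMP, ...) has no feasible solution."""


class CapabilityError(NihbaError):
    """A requested computation exceeds a guard or needs an absent backend."""
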