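"""Exception types shared across the package."""


class ConfigurationError(Exception):
    """A configuration value is missing, unresolvable, or inconsistent."""


class ConvergenceError(RuntimeError):
    """An iterative numerical procedure failed to converge."""


class InputError(Exception):
    """An input file or table is unreadable or violates its schema."""
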