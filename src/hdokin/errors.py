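"""Exception hierarchy shared across the package.

All user-facing errors derive from :class:`HdokinError` so callers (and the
CLI) can distinguish input-validation problems from numerical failures.
"""


class HdokinError(Exception):
    """Base class for all hdokin errors."""


class InputError(HdokinError, ValueError):
    """Invalid user input: bad values, missing columns, malformed config."""


class ConfigurationError(InputError):
    """A scheme/configuration references something that is not declared."""


class UnsupportedSchemeError(InputError):
    """The reaction network falls outside the supported class (e.g. cyclic)."""


class ConvergenceError(HdokinError, RuntimeError):
    """A fit failed to converge where a hard failure was requested."""


class InfeasibleError(HdokinError, ValueError):
    """A solver found no positive solution; carries a diagnostic message."""
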