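"""Exception hierarchy for lmerbin."""


class LmerbinError(Exception):
    """Base class for all lmerbin errors."""


class InputError(LmerbinError):
    """Malformed or unusable input data (sequences, tables, files)."""


class ParameterError(LmerbinError):
    """A parameter violates its documented constraints."""


class DegenerateFragmentError(InputError):
    """A fragment yields no valid counting windows and cannot be normalized."""
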