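"""Exception hierarchy shared by all subpackages.

The CLI maps these onto distinct exit codes so that shell pipelines can
branch on the kind of failure (usage vs. data vs. numerical).
"""


class IasplsError(Exception):
    """Base class for all package-specific failures."""


class DataError(IasplsError):
    """Malformed, inconsistent or out-of-contract input data."""


class NumericalError(IasplsError):
    """A numerical routine could not produce a valid result."""
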