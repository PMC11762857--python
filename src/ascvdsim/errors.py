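"""Exception hierarchy.

All package-specific failures derive from :class:`AscvdSimError` so callers
can catch one base class; the subclasses mirror the three failure modes the
public operations distinguish (bad configuration, bad simulation state, bad
numeric domain).
"""


class AscvdSimError(Exception):
    """Base class for all errors raised by ascvdsim."""


class ConfigurationError(AscvdSimError):
    """A parameter file, coefficient file or config object is invalid."""


class StateError(AscvdSimError):
    """An operation was applied to a profile in an illegal state (e.g. dead)."""


class DomainError(AscvdSimError, ValueError):
    """A numeric argument lies outside its mathematical domain."""
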