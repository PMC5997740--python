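"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A scenario, chromosome table or CLI option is invalid."""


class InvariantViolation(ValueError):
    """An operation was called with arguments that break a model invariant."""


class StateCorruptionError(RuntimeError):
    """Lattice or population bookkeeping was driven into an illegal state."""
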