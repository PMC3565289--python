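"""Exception hierarchy shared across the package."""


class MqsarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MqsarError):
    """A structure file could not be parsed (message names the offending line)."""


class EmptyInputError(MqsarError):
    """An input contained no usable records (e.g. a PDB file with zero atoms)."""


class PreconditionError(MqsarError, ValueError):
    """An operation was called with arguments violating its contract."""


class ParameterMissingError(MqsarError, KeyError):
    """A force-field or solvation parameter is not available for an element."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class NoLigandError(MqsarError):
    """No ligand-like molecule could be identified (apo structure)."""


class SelectionError(MqsarError):
    """An atom or residue selection did not match the topology."""


class InconsistentTrajectoryError(MqsarError):
    """Trajectory frames do not share one topology."""


class SingularityError(MqsarError, ZeroDivisionError):
    """A pair energy was requested at zero interatomic distance."""


class UndefinedMetricError(MqsarError, ZeroDivisionError):
    """A validation metric is undefined (zero denominator)."""


class FixtureCorruptionError(MqsarError):
    """A packaged data fixture failed its checksum verification."""
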