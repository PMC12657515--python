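"""Exception hierarchy."""


class QmmdockError(Exception):
    """Base class for all package errors."""


class FormatError(QmmdockError):
    """Malformed input file (PDB/SDF/MOL2/TSV)."""


class EmptyInputError(QmmdockError):
    """Structurally valid input that contains no atoms/records."""


class ParameterError(QmmdockError):
    """Missing or inconsistent force-field-like parameters."""


class ConfigError(QmmdockError):
    """Invalid run configuration."""


class TopologyError(QmmdockError):
    """Unsupported molecular topology (e.g. boundary cut through a ring)."""


class ConvergenceError(QmmdockError):
    """A solver or engine failed to converge."""


class SingularityError(QmmdockError):
    """Numerical singularity (e.g. two point charges at one position)."""
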