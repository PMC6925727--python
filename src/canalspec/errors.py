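"""Exception hierarchy for canalspec."""


class CanalspecError(Exception):
    """Base class for all canalspec errors."""


class MeshFormatError(CanalspecError):
    """A mesh file could not be parsed in the requested dialect."""


class MeshValidationError(CanalspecError):
    """A mesh violates the closed-manifold / orientation contract."""


class GeometryError(CanalspecError):
    """A geometric construction failed (empty section, bad loft, ...)."""


class SolverError(CanalspecError):
    """A linear or eigenvalue solve failed to converge."""


class ConditioningError(SolverError):
    """A matrix was numerically singular or indefinite."""
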