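"""Exception types shared across the package."""


class MeshStructureError(ValueError):
    """The surface mesh violates a structural precondition (non-manifold,
    dangling faces, inconsistent boundary)."""


class ParameterError(ValueError):
    """A parameter is outside its valid range for the given input."""


class NoPathError(RuntimeError):
    """The requested pair of nodes is not connected in the graph."""


class PlanningFailureError(RuntimeError):
    """Virtual-ablation planning could not produce a valid plan."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on the given input (e.g. zero variance)."""
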