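"""Exception hierarchy shared across the package."""


class CPCausalError(Exception):
    """Base class for all package-specific errors."""


class UnknownNodeError(CPCausalError, KeyError):
    """A node name was used that is not declared in the graph."""

    def __init__(self, node):
        super().__init__(node)
        self.node = node

    def __str__(self) -> str:  # KeyError repr-quotes; keep a readable message
        return f"unknown node: {self.node!r}"


class CyclicGraphError(CPCausalError, ValueError):
    """An edge set contains a directed cycle (causal models must be acyclic)."""


class GraphQueryError(CPCausalError, ValueError):
    """A separation/adjustment query violated its preconditions."""


class PathBudgetError(CPCausalError, RuntimeError):
    """The brute-force path enumerator exceeded its path budget."""


class NotIdentifiableError(CPCausalError, ValueError):
    """No observed covariate adjustment set identifies the requested effect."""


class ModelConfigError(CPCausalError, ValueError):
    """A causal-model configuration failed validation."""


class SchemaError(CPCausalError, ValueError):
    """An input table does not match the model's variable schema."""


class EstimationError(CPCausalError, ValueError):
    """A statistical routine received a degenerate design (collinearity, zero
    variance, missing values)."""
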