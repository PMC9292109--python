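"""The cerebral-palsy impairment model shipped as data.

The builtin model (id ``"cp-impairment"``) encodes the hypothesized causal
structure linking a brain injury and its primary neurological impairments
(selective and dynamic motor control, strength, spasticity) through secondary
orthopedic deformity (joint contractures, long-bone torsions) and gait
quality (GDI) to gross motor function (GMFM-66), with age as an exogenous
driver.  Four nodes are latent — the injury itself, overall motor control,
and the shared tendencies toward contracture and torsion — and induce
dependence among their observed children without being measurable.

Two deliberate structural choices worth knowing about:

* no ``Age -> Strength`` edge: the strength scale is age-normalized, so age
  effects are removed at measurement;
* no direct torsion -> GMFM edges: long-bone torsion is assumed to affect
  gross motor function only through the gait pattern.

Variable metadata carries the measurement conventions of raw clinic data:
which variables are coded so that a *larger* raw value means *more*
impairment (``sign_flip``), and the typically-developing reference values
already subtracted from goniometry/torsion measures (``td_offset``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .errors import ModelConfigError
from .graph import CausalGraph

__all__ = ["VariableMeta", "ModelConfig", "load_model", "export_dot", "BUILTIN_MODELS"]

OUTCOME = "GMFM"

#: Canonical edge list of the builtin impairment model.
_CANONICAL_LATENT = ("Contracture", "Injury", "MC", "Torsion")

_NEURO = ("Age", "DMC", "SCALE", "Spasticity", "Strength")
_CONTRACTURES = ("AnkleDF", "HipExt", "KneeExt", "Popliteal")
_TORSIONS = ("FemRot", "TibRot")


def _canonical_edges() -> list[tuple[str, str]]:
    edges: list[tuple[str, str]] = [
        ("Injury", "MC"),
        ("Injury", "Strength"),
        ("Injury", "Spasticity"),
        ("MC", "SCALE"),
        ("MC", "DMC"),
        ("MC", "Strength"),
        ("Age", "SCALE"),
        ("Age", "DMC"),
        ("Age", "Spasticity"),
        # note: no Age -> Strength (strength is age-normalized at measurement)
    ]
    for c in _CONTRACTURES:
        edges.append(("Contracture", c))
        edges += [(p, c) for p in _NEURO]
    for t in _TORSIONS:
        edges.append(("Torsion", t))
        edges += [(p, t) for p in _NEURO]
    edges += [(p, "GDI") for p in _NEURO + _CONTRACTURES + _TORSIONS]
    # torsions reach GMFM only through gait pattern: no torsion -> GMFM edges
    edges += [(p, "GMFM") for p in _NEURO + _CONTRACTURES + ("GDI",)]
    return edges


def _builtin_graph() -> CausalGraph:
    nodes = list(_CANONICAL_LATENT) + list(_NEURO) + list(_CONTRACTURES) + list(
        _TORSIONS
    ) + ["GDI", OUTCOME]
    return CausalGraph(nodes, _canonical_edges(), _CANONICAL_LATENT)


@dataclass(frozen=True)
class VariableMeta:
    """Measurement metadata for one observed model variable.

    ``sign_flip`` is true when a larger raw value means more impairment
    (spasticity, inwardly-directed torsion); such columns are negated during
    standardization so that, post-transform, larger always means better
    function.  ``td_offset`` is the typically-developing reference (degrees)
    subtracted from raw goniometry/torsion readings to express them as
    deviations from typical; zero for scale variables.
    """

    name: str
    role: str  # "exposure" | "outcome" | "age"
    units: str
    sign_flip: bool = False
    td_offset: float = 0.0
    allowed_range: Optional[tuple[float, float]] = None


#: Raw-data conventions: contractures are recorded as negative deviations
#: (more negative = more contracture, so no flip), spasticity and inward
#: torsion increase with impairment (flip).
_BUILTIN_VARIABLES = (
    VariableMeta("Age", "age", "years", False, 0.0, (0.0, 25.0)),
    VariableMeta("SCALE", "exposure", "scale points", False, 0.0, (0.0, 10.0)),
    VariableMeta("DMC", "exposure", "index points", False, 0.0, (20.0, 140.0)),
    VariableMeta("Strength", "exposure", "scale points", False, 0.0, (0.0, 5.0)),
    VariableMeta("Spasticity", "exposure", "scale points", True, 0.0, (0.0, 5.0)),
    VariableMeta("AnkleDF", "exposure", "deg", False, 21.3, (-60.0, 30.0)),
    VariableMeta("KneeExt", "exposure", "deg", False, 4.0, (-45.0, 30.0)),
    VariableMeta("Popliteal", "exposure", "deg", False, 25.6, (-90.0, 30.0)),
    VariableMeta("HipExt", "exposure", "deg", False, 0.0, (-45.0, 30.0)),
    VariableMeta("FemRot", "exposure", "deg", True, 26.9, (-80.0, 80.0)),
    VariableMeta("TibRot", "exposure", "deg", True, 16.0, (-60.0, 60.0)),
    VariableMeta("GDI", "exposure", "index points", False, 0.0, (20.0, 140.0)),
    VariableMeta(OUTCOME, "outcome", "GMFM-66 points", False, 0.0, (0.0, 100.0)),
)


@dataclass
class ModelConfig:
    """A validated causal model: graph + per-variable measurement metadata."""

    name: str
    graph: CausalGraph
    variables: dict[str, VariableMeta] = field(default_factory=dict)
    outcome: str = OUTCOME

    def __post_init__(self):
        if self.outcome not in self.graph:
            raise ModelConfigError(f"outcome {self.outcome!r} missing from graph")
        if self.graph.is_latent(self.outcome):
            raise ModelConfigError("outcome cannot be latent")
        missing = set(self.graph.observed) - set(self.variables)
        if missing:
            raise ModelConfigError(
                f"no variable metadata for observed nodes: {sorted(missing)}"
            )
        extra = set(self.variables) - set(self.graph.observed)
        if extra:
            raise ModelConfigError(
                f"metadata for undeclared/latent nodes: {sorted(extra)}"
            )

    @property
    def exposures(self) -> tuple[str, ...]:
        """Observed non-outcome variables, in sorted order."""
        return tuple(n for n in self.graph.observed if n != self.outcome)

    def meta(self, name: str) -> VariableMeta:
        return self.variables[name]


def _builtin_config() -> ModelConfig:
    cfg = ModelConfig(
        "cp-impairment",
        _builtin_graph(),
        {v.name: v for v in _BUILTIN_VARIABLES},
    )
    _validate_builtin(cfg)
    return cfg


def _validate_builtin(cfg: ModelConfig) -> None:
    """Check the builtin against its embedded canonical copy."""
    if set(cfg.graph.edges) != set(_canonical_edges()):
        raise ModelConfigError("builtin model drifted from its canonical edge list")
    if cfg.graph.latent != _CANONICAL_LATENT:
        raise ModelConfigError("builtin latent set must be exactly "
                               f"{_CANONICAL_LATENT}")
    for meta in cfg.variables.values():
        if meta.name in ("Age", "SCALE", "DMC", "Strength", "GDI", OUTCOME):
            if meta.sign_flip:
                raise ModelConfigError(
                    f"{meta.name} is already oriented larger=better; no flip"
                )


BUILTIN_MODELS = ("cp-impairment",)
_BUILTIN_ALIASES = {"cp-impairment", "builtin", "default"}

_ALLOWED_TOP_KEYS = {"name", "outcome", "latent", "edges", "variables"}
_ALLOWED_VAR_KEYS = {"role", "units", "sign_flip", "td_offset", "range"}


def load_model(source: Union[str, "io.TextIOBase", None] = None) -> ModelConfig:
    """Load a model config from a builtin name, a YAML path, or a stream.

    ``None`` or any of ``"cp-impairment"/"builtin"/"default"`` returns the
    embedded impairment model.  A YAML config needs ``edges`` (``"A -> B"``
    strings or two-element lists) and may declare ``latent``, ``outcome``,
    ``name`` and per-variable ``variables`` metadata; unknown keys are
    rejected outright.
    """
    if source is None or (isinstance(source, str) and source in _BUILTIN_ALIASES):
        return _builtin_config()
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, dict):
        raise ModelConfigError("model config must be a mapping")
    unknown = set(raw) - _ALLOWED_TOP_KEYS
    if unknown:
        raise ModelConfigError(f"unknown config keys: {sorted(unknown)}")
    if "edges" not in raw:
        raise ModelConfigError("config missing required key 'edges'")
    edges = []
    for item in raw["edges"]:
        if isinstance(item, str):
            if "->" not in item:
                raise ModelConfigError(f"edge {item!r} is not of the form 'A -> B'")
            cause, effect = (s.strip() for s in item.split("->", 1))
        elif isinstance(item, (list, tuple)) and len(item) == 2:
            cause, effect = (str(s) for s in item)
        else:
            raise ModelConfigError(f"unparseable edge entry: {item!r}")
        edges.append((cause, effect))
    latent = [str(v) for v in raw.get("latent", [])]
    nodes = list(dict.fromkeys(
        [n for e in edges for n in e] + latent
    ))
    graph = CausalGraph(nodes, edges, latent)
    outcome = str(raw.get("outcome", OUTCOME))
    defaults = {v.name: v for v in _BUILTIN_VARIABLES}
    variables: dict[str, VariableMeta] = {}
    var_cfg = raw.get("variables", {}) or {}
    if not isinstance(var_cfg, dict):
        raise ModelConfigError("'variables' must be a mapping")
    for node in graph.observed:
        entry = var_cfg.get(node, {})
        if entry is None:
            entry = {}
        unknown = set(entry) - _ALLOWED_VAR_KEYS
        if unknown:
            raise ModelConfigError(
                f"unknown keys for variable {node!r}: {sorted(unknown)}"
            )
        base = defaults.get(node)
        role = entry.get(
            "role", base.role if base else ("outcome" if node == outcome else "exposure")
        )
        rng = entry.get("range", base.allowed_range if base else None)
        variables[node] = VariableMeta(
            name=node,
            role=role,
            units=str(entry.get("units", base.units if base else "")),
            sign_flip=bool(entry.get("sign_flip", base.sign_flip if base else False)),
            td_offset=float(entry.get("td_offset", base.td_offset if base else 0.0)),
            allowed_range=tuple(rng) if rng is not None else None,
        )
    stray = set(var_cfg) - set(graph.observed)
    if stray:
        raise ModelConfigError(
            f"variable metadata for unknown/latent nodes: {sorted(stray)}"
        )
    return ModelConfig(str(raw.get("name", "custom")), graph, variables, outcome)


def export_dot(config: ModelConfig) -> str:
    """DOT rendering of a model's graph (latents dashed, deterministic order)."""
    return config.graph.to_dot(name=config.name.replace("-", "_"))
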