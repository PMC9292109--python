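"""Testable implications and covariate adjustment sets of a causal DAG.

Two questions are answered here:

1. *Which conditional independencies does the model imply among the observed
   variables?*  These are the model's falsifiable predictions: each one is a
   partial correlation that must be (statistically) zero if the hypothesized
   structure is right.  We use the missing-edge basis: one statement per
   non-adjacent observed pair that admits an observed separating set, with a
   deterministic minimal separator.

2. *Which covariates must a regression adjust for so that a coefficient can
   be read causally?*  Total effects use the generalized adjustment
   criterion (no descendant of a mediator in the set; all non-causal paths
   blocked in the proper backdoor graph); controlled direct effects use the
   single-door criterion (all paths other than the direct edge blocked, no
   descendant of the outcome conditioned on).

Latent nodes are never eligible for conditioning or adjustment — they were
not measured.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import GraphQueryError, NotIdentifiableError
from .graph import CausalGraph

__all__ = [
    "CIStatement",
    "AdjustmentResult",
    "implied_independencies",
    "enumerate_all_independencies",
    "minimal_separator",
    "verify_adjustment",
    "adjustment_sets",
    "has_open_noncausal_path",
    "proper_causal_nodes",
    "forbidden_for_total",
]

_MAX_ENUM_CANDIDATES = 16  # 2**16 subsets is the enumeration ceiling


@dataclass(frozen=True)
class CIStatement:
    """A claim ``x _||_ y | given`` over observed variables.

    Unordered in ``(x, y)``: the pair is stored sorted so two statements
    differing only in orientation compare equal.
    """

    x: str
    y: str
    given: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.x == self.y:
            raise GraphQueryError("CI statement requires distinct variables")
        if self.x in self.given or self.y in self.given:
            raise GraphQueryError("conditioning set overlaps the tested pair")
        a, b = sorted((self.x, self.y))
        object.__setattr__(self, "x", a)
        object.__setattr__(self, "y", b)
        object.__setattr__(self, "given", frozenset(self.given))

    def __str__(self) -> str:
        cond = ", ".join(sorted(self.given))
        return f"{self.x} _||_ {self.y}" + (f" | {cond}" if cond else "")

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "given": sorted(self.given)}


@dataclass
class AdjustmentResult:
    """All minimal observed adjustment sets for one (exposure, outcome) query."""

    exposure: str
    outcome: str
    effect_type: str  # "total" | "direct"
    sets: list[frozenset[str]] = field(default_factory=list)
    chosen: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "effect_type": self.effect_type,
            "sets": [sorted(s) for s in self.sets],
            "chosen": sorted(self.chosen),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# separators


def _observed_only(g: CausalGraph, z: Iterable[str], what: str) -> set[str]:
    z = set(z)
    for v in z:
        if g.is_latent(v):
            raise GraphQueryError(f"latent node {v!r} not allowed in {what}")
    return z


def minimal_separator(
    g: CausalGraph,
    x: str,
    y: str,
    candidates: Optional[Iterable[str]] = None,
) -> Optional[frozenset[str]]:
    """A minimal subset of ``candidates`` d-separating ``x`` and ``y``.

    Exploits the standard ancestral reduction: some subset of the candidate
    pool separates the pair iff the pool restricted to ancestors of
    ``{x, y}`` does.  Starting from that restriction, elements are greedily
    deleted in lexicographic order while separation holds, giving a
    deterministic (inclusion-)minimal separator.  Returns ``None`` when no
    candidate subset separates the pair.
    """
    if g.has_edge(x, y) or g.has_edge(y, x):
        raise GraphQueryError(f"{x!r} and {y!r} are adjacent; no separator exists")
    if candidates is None:
        candidates = set(g.observed) - {x, y}
    candidates = _observed_only(g, candidates, "candidate separators") - {x, y}
    anc = g.ancestors(x) | g.ancestors(y)
    z = set(candidates) & anc
    if not g.d_separated(x, y, z):
        return None
    for v in sorted(z):
        trial = z - {v}
        if g.d_separated(x, y, trial):
            z = trial
    return frozenset(z)


def implied_independencies(g: CausalGraph) -> list[CIStatement]:
    """The model's testable implications, one per separable non-adjacent pair.

    For every unordered pair of non-adjacent *observed* nodes, emit one
    :class:`CIStatement` with a deterministic minimal observed separating
    set, if any observed set separates the pair; pairs whose dependence is
    forced by latent structure are omitted.  Output sorted by ``(x, y)``.
    """
    obs = g.observed
    if len(obs) < 2:
        raise GraphQueryError("need at least two observed nodes")
    out: list[CIStatement] = []
    for x, y in itertools.combinations(sorted(obs), 2):
        if g.has_edge(x, y) or g.has_edge(y, x):
            continue
        sep = minimal_separator(g, x, y)
        if sep is not None:
            out.append(CIStatement(x, y, sep))
    return out


def enumerate_all_independencies(
    g: CausalGraph, max_given: Optional[int] = None
) -> list[CIStatement]:
    """Every observed conditional independence the graph implies.

    Exponential in the number of observed nodes — exposed for small graphs
    and completeness checks; :func:`implied_independencies` (the missing-edge
    basis) is the default notion of "the model's implications".
    """
    obs = sorted(g.observed)
    out = []
    for x, y in itertools.combinations(obs, 2):
        pool = [v for v in obs if v not in (x, y)]
        top = len(pool) if max_given is None else min(max_given, len(pool))
        for k in range(top + 1):
            for z in itertools.combinations(pool, k):
                if g.d_separated(x, y, z):
                    out.append(CIStatement(x, y, frozenset(z)))
    return out


# ---------------------------------------------------------------------------
# adjustment


def proper_causal_nodes(g: CausalGraph, exposure: str, outcome: str) -> set[str]:
    """Nodes other than the exposure lying on a directed exposure→outcome path."""
    return (g.descendants(exposure) - {exposure}) & g.ancestors(outcome)


def forbidden_for_total(g: CausalGraph, exposure: str, outcome: str) -> set[str]:
    """Nodes that must not be adjusted for when targeting the total effect:
    the exposure itself and every descendant of a node on a proper causal
    path (conditioning on these blocks or biases transmitted effect)."""
    forb = {exposure}
    for m in proper_causal_nodes(g, exposure, outcome):
        forb |= g.descendants(m)
    return forb


def _proper_backdoor_graph(
    g: CausalGraph, exposure: str, outcome: str
) -> CausalGraph:
    cn = proper_causal_nodes(g, exposure, outcome)
    drop = [(exposure, c) for c in g.children(exposure) if c in cn]
    return g.subgraph_without_edges(drop)


def verify_adjustment(
    g: CausalGraph,
    exposure: str,
    outcome: str,
    z: Iterable[str],
    effect_type: str = "total",
) -> bool:
    """Does ``z`` identify the requested effect of ``exposure`` on ``outcome``?

    ``total``
        Generalized adjustment criterion: ``z`` contains no forbidden node
        (descendant of a proper mediator, or the exposure) and d-separates
        exposure from outcome in the proper backdoor graph — i.e. it blocks
        every non-causal path while leaving every causal path intact.
    ``direct``
        Single-door criterion for the controlled direct effect under
        linearity: ``z`` contains no descendant of the outcome, and
        d-separates exposure from outcome once the direct edge (if present)
        is removed — mediated and confounding paths are all blocked, leaving
        only the direct edge.
    """
    if exposure == outcome:
        raise GraphQueryError("exposure and outcome must be distinct")
    for v in (exposure, outcome):
        if g.is_latent(v):
            raise GraphQueryError(f"{v!r} is latent; effects are defined on measures")
    z = _observed_only(g, z, "an adjustment set")
    if z & {exposure, outcome}:
        raise GraphQueryError("adjustment set overlaps exposure/outcome")
    if effect_type == "total":
        if z & forbidden_for_total(g, exposure, outcome):
            return False
        pbd = _proper_backdoor_graph(g, exposure, outcome)
        return pbd.d_separated(exposure, outcome, z)
    if effect_type == "direct":
        if z & g.descendants(outcome):
            return False
        ge = (
            g.subgraph_without_edges([(exposure, outcome)])
            if g.has_edge(exposure, outcome)
            else g
        )
        return ge.d_separated(exposure, outcome, z)
    raise GraphQueryError(f"unknown effect_type {effect_type!r}")


def adjustment_sets(
    g: CausalGraph,
    exposure: str,
    outcome: str,
    effect_type: str = "total",
) -> AdjustmentResult:
    """Enumerate all minimal observed adjustment sets; pick one deterministically.

    ``chosen`` is the smallest valid minimal set, ties broken by sorted
    lexicographic comparison.  Raises :class:`NotIdentifiableError` when no
    observed set satisfies the criterion (distinct from a valid empty set).
    """
    if effect_type == "total":
        banned = forbidden_for_total(g, exposure, outcome)
        check_graph = _proper_backdoor_graph(g, exposure, outcome)
    elif effect_type == "direct":
        banned = g.descendants(outcome) | {exposure}
        check_graph = (
            g.subgraph_without_edges([(exposure, outcome)])
            if g.has_edge(exposure, outcome)
            else g
        )
    else:
        raise GraphQueryError(f"unknown effect_type {effect_type!r}")
    pool = sorted(set(g.observed) - {exposure, outcome} - banned)
    if len(pool) > _MAX_ENUM_CANDIDATES:
        raise GraphQueryError(
            f"{len(pool)} candidate covariates exceed the enumeration limit "
            f"({_MAX_ENUM_CANDIDATES})"
        )
    valid: list[frozenset[str]] = []
    for k in range(len(pool) + 1):
        for z in itertools.combinations(pool, k):
            zs = frozenset(z)
            if any(v <= zs for v in valid):
                continue  # a valid subset exists, zs cannot be minimal
            if check_graph.d_separated(exposure, outcome, zs):
                valid.append(zs)
    if not valid:
        raise NotIdentifiableError(
            f"{effect_type} effect of {exposure!r} on {outcome!r} is not "
            "identifiable by covariate adjustment over observed variables"
        )
    chosen = min(valid, key=lambda s: (len(s), tuple(sorted(s))))
    valid.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return AdjustmentResult(exposure, outcome, effect_type, valid, chosen)


def has_open_noncausal_path(g: CausalGraph, exposure: str, outcome: str) -> bool:
    """True iff an unblocked (given nothing) non-causal path links the pair.

    Exactly the condition under which an unadjusted bivariate regression
    slope differs from the total causal effect.
    """
    pbd = _proper_backdoor_graph(g, exposure, outcome)
    return not pbd.d_separated(exposure, outcome, ())
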