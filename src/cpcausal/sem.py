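"""Linear-Gaussian structural equation simulation with closed-form truth.

Every node is generated in topological order as

    value = intercept + sum(coeff * parent) + Normal(0, noise_sd)

so the joint distribution is multivariate normal with mean
``mu = (I - B')^-1 c`` and covariance ``Sigma = (I - B')^-1 Omega (I - B')^-T``
where ``B[j, i]`` holds the coefficient of edge j -> i and ``Omega`` is the
diagonal of noise variances.  Because the distribution is Gaussian and
generated faithfully from the graph, every d-separation of the graph is an
*exact* conditional independence of the simulated data — which is what makes
the simulator a usable oracle for the whole analysis layer.

The default specification emulates a gait-lab cohort of children with
spastic cerebral palsy: coefficients of the equations feeding GMFM-66 are
taken from the published per-unit predictive model, upstream coefficients
are fixed package calibration constants, and intercepts and noise SDs are
solved so that the implied marginal means and SDs approximate the published
cohort table (GMFCS level II for the default; ``cohort_fixture`` selects
level I, II or III).  The calibration is a fixture for testing the pipeline,
not a claim about any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .data import VariableTable
from .errors import ModelConfigError
from .graph import CausalGraph
from .model import ModelConfig, load_model

__all__ = [
    "SEMSpec",
    "SimulatedCohort",
    "simulate",
    "true_total_effect",
    "true_bivariate_effect",
    "default_sem",
    "cohort_fixture",
    "TABLE_TARGETS",
]

#: Marginal calibration targets (mean, SD) per severity level, in raw
#: clinic conventions (contractures negative; torsions inward-positive).
TABLE_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    "I": {
        "Age": (10.5, 3.5), "DMC": (91.0, 10.0), "GDI": (82.0, 10.7),
        "SCALE": (6.8, 1.4), "Spasticity": (1.6, 0.9), "Strength": (4.6, 0.3),
        "GMFM": (87.0, 6.2), "AnkleDF": (-17.0, 6.1), "KneeExt": (1.0, 4.9),
        "Popliteal": (-13.0, 17.4), "HipExt": (-1.0, 2.7),
        "FemRot": (-1.0, 24.1), "TibRot": (-1.0, 5.8),
    },
    "II": {
        "Age": (11.6, 3.5), "DMC": (80.0, 12.2), "GDI": (71.0, 9.4),
        "SCALE": (5.2, 1.4), "Spasticity": (2.1, 1.1), "Strength": (4.2, 0.5),
        "GMFM": (73.0, 7.0), "AnkleDF": (-20.0, 8.1), "KneeExt": (-2.0, 7.2),
        "Popliteal": (-24.0, 18.7), "HipExt": (-4.0, 5.1),
        "FemRot": (-4.0, 25.7), "TibRot": (-2.0, 6.7),
    },
    "III": {
        "Age": (10.9, 3.3), "DMC": (66.0, 9.8), "GDI": (63.0, 8.5),
        "SCALE": (3.0, 1.4), "Spasticity": (2.9, 1.1), "Strength": (3.5, 0.6),
        "GMFM": (57.0, 4.6), "AnkleDF": (-20.0, 8.2), "KneeExt": (-7.0, 8.8),
        "Popliteal": (-31.0, 18.3), "HipExt": (-8.0, 7.6),
        "FemRot": (-11.0, 24.9), "TibRot": (-3.0, 7.0),
    },
}

#: Latent scales are unit-SD by construction.
_LATENT_TARGETS = {
    "Injury": (0.0, 1.0), "MC": (0.0, 1.0),
    "Contracture": (0.0, 1.0), "Torsion": (0.0, 1.0),
}

#: Default edge coefficients, raw units.  The equations feeding GMFM carry
#: the published per-unit betas (contracture betas negated: raw contracture
#: deviations are negative-is-worse while the published model counts
#: limitation degrees); everything upstream is package calibration chosen to
#: give plausible confounding strength and marginal spread.
_DEFAULT_COEFFS: dict[tuple[str, str], float] = {
    ("Injury", "MC"): -0.8,
    ("Injury", "Strength"): -0.15,
    ("Injury", "Spasticity"): 0.7,
    ("MC", "SCALE"): 0.9,
    ("MC", "DMC"): 8.0,
    ("MC", "Strength"): 0.25,
    ("Age", "SCALE"): 0.05,
    ("Age", "DMC"): 0.3,
    ("Age", "Spasticity"): 0.03,
    # contractures (raw: negative = more contracture)
    ("Contracture", "AnkleDF"): -4.0,
    ("Contracture", "KneeExt"): -3.5,
    ("Contracture", "Popliteal"): -9.0,
    ("Contracture", "HipExt"): -2.5,
    ("Strength", "AnkleDF"): 3.0, ("Strength", "KneeExt"): 3.0,
    ("Strength", "Popliteal"): 6.0, ("Strength", "HipExt"): 2.0,
    ("Spasticity", "AnkleDF"): -1.5, ("Spasticity", "KneeExt"): -1.5,
    ("Spasticity", "Popliteal"): -3.0, ("Spasticity", "HipExt"): -1.0,
    ("DMC", "AnkleDF"): 0.1, ("DMC", "KneeExt"): 0.1,
    ("DMC", "Popliteal"): 0.2, ("DMC", "HipExt"): 0.05,
    ("SCALE", "AnkleDF"): 0.8, ("SCALE", "KneeExt"): 0.8,
    ("SCALE", "Popliteal"): 1.5, ("SCALE", "HipExt"): 0.5,
    ("Age", "AnkleDF"): -0.5, ("Age", "KneeExt"): -0.4,
    ("Age", "Popliteal"): -1.0, ("Age", "HipExt"): -0.3,
    # torsions (raw: inward-positive)
    ("Torsion", "TibRot"): 4.0, ("Torsion", "FemRot"): 15.0,
    ("Strength", "TibRot"): -1.5, ("Strength", "FemRot"): -5.0,
    ("Spasticity", "TibRot"): 1.0, ("Spasticity", "FemRot"): 3.0,
    ("DMC", "TibRot"): -0.05, ("DMC", "FemRot"): -0.2,
    ("SCALE", "TibRot"): -0.5, ("SCALE", "FemRot"): -2.0,
    ("Age", "TibRot"): -0.2, ("Age", "FemRot"): -0.5,
    # gait pattern
    ("Strength", "GDI"): 3.0, ("Spasticity", "GDI"): -1.0,
    ("DMC", "GDI"): 0.25, ("SCALE", "GDI"): 1.0, ("Age", "GDI"): 0.1,
    ("AnkleDF", "GDI"): 0.15, ("KneeExt", "GDI"): 0.1,
    ("Popliteal", "GDI"): 0.05, ("HipExt", "GDI"): 0.2,
    ("TibRot", "GDI"): -0.1, ("FemRot", "GDI"): -0.05,
    # gross motor function: published per-unit betas (contractures negated)
    ("Age", "GMFM"): 0.08, ("SCALE", "GMFM"): 2.3, ("DMC", "GMFM"): 0.24,
    ("Strength", "GMFM"): 4.5, ("Spasticity", "GMFM"): -0.57,
    ("GDI", "GMFM"): 0.17,
    ("AnkleDF", "GMFM"): 0.13, ("KneeExt", "GMFM"): 0.11,
    ("Popliteal", "GMFM"): 0.01, ("HipExt", "GMFM"): 0.17,
}

_NOISE_FLOOR_FRAC = 0.15  # noise SD never below this fraction of the target SD


@dataclass
class SEMSpec:
    """A fully parameterized linear-Gaussian SEM over a causal graph.

    ``node_mean`` holds per-node *intercepts* (the constant in each
    structural equation), not marginal means; ``implied_mean`` gives the
    latter.  ``seed`` is the default stream for :func:`simulate` and expands
    deterministically into independent per-node substreams.
    """

    graph: CausalGraph
    edge_coefficients: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    node_mean: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        edges = set(self.graph.edges)
        keys = set(self.edge_coefficients)
        if keys != edges:
            missing = sorted(edges - keys)
            extra = sorted(keys - edges)
            raise ModelConfigError(
                f"edge coefficient keys must match graph edges exactly; "
                f"missing={missing} extra={extra}"
            )
        bad = sorted(set(self.graph.nodes) - set(self.noise_sd))
        if bad:
            raise ModelConfigError(f"missing noise_sd for nodes: {bad}")
        nonpos = sorted(n for n, s in self.noise_sd.items() if not s > 0)
        if nonpos:
            raise ModelConfigError(f"noise_sd must be positive for: {nonpos}")
        self.node_mean = {n: float(self.node_mean.get(n, 0.0))
                         for n in self.graph.nodes}
        # positive noise on every node already forces positive definiteness,
        # but verify numerically so a corrupt spec fails loudly here.
        w = np.linalg.eigvalsh(self.implied_cov().to_numpy())
        if w.min() <= 0:
            raise ModelConfigError("implied covariance is not positive definite")

    # -- closed-form moments -----------------------------------------------

    def _matrices(self):
        nodes = list(self.graph.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        k = len(nodes)
        B = np.zeros((k, k))  # B[i, j] = coeff of edge j -> i
        for (c, e), b in self.edge_coefficients.items():
            B[idx[e], idx[c]] = b
        omega = np.diag([self.noise_sd[n] ** 2 for n in nodes])
        return nodes, B, omega

    def implied_cov(self) -> pd.DataFrame:
        """Model-implied covariance over all nodes (latents included)."""
        nodes, B, omega = self._matrices()
        a = np.linalg.inv(np.eye(len(nodes)) - B)
        return pd.DataFrame(a @ omega @ a.T, index=nodes, columns=nodes)

    def implied_mean(self) -> pd.Series:
        nodes, B, _ = self._matrices()
        c = np.array([self.node_mean[n] for n in nodes])
        return pd.Series(np.linalg.solve(np.eye(len(nodes)) - B, c), index=nodes)

    def implied_sd(self) -> pd.Series:
        return np.sqrt(pd.Series(np.diag(self.implied_cov()),
                                 index=self.implied_cov().index))

    def with_seed(self, seed: int) -> "SEMSpec":
        return replace(self, edge_coefficients=dict(self.edge_coefficients),
                       noise_sd=dict(self.noise_sd),
                       node_mean=dict(self.node_mean), seed=seed)

    # -- calibration --------------------------------------------------------

    @classmethod
    def from_marginal_targets(
        cls,
        graph: CausalGraph,
        coefficients: dict[tuple[str, str], float],
        target_mean: dict[str, float],
        target_sd: dict[str, float],
        seed: int = 0,
    ) -> "SEMSpec":
        """Solve intercepts and noise SDs so implied marginals hit targets.

        Walking the graph in topological order, each node's intercept is set
        so its implied mean equals ``target_mean[node]`` and its noise
        variance to ``target_sd**2`` minus the variance already transmitted
        by its parents.  When parents alone exceed the target variance the
        noise is floored at ``0.15 * target_sd`` and the implied SD ends up
        above target; means are always exact.
        """
        noise: dict[str, float] = {}
        intercept: dict[str, float] = {}
        mean: dict[str, float] = {}
        order = graph.topological_order()
        cov = pd.DataFrame(0.0, index=order, columns=order)
        for node in order:
            pa = sorted(graph.parents(node))
            b = np.array([coefficients[(p, node)] for p in pa])
            mu = float(b @ np.array([mean[p] for p in pa])) if pa else 0.0
            intercept[node] = target_mean[node] - mu
            mean[node] = target_mean[node]
            path_var = float(b @ cov.loc[pa, pa].to_numpy() @ b) if pa else 0.0
            floor = (_NOISE_FLOOR_FRAC * target_sd[node]) ** 2
            noise_var = max(target_sd[node] ** 2 - path_var, floor)
            noise[node] = float(np.sqrt(noise_var))
            # extend covariance with the new node
            if pa:
                cross = cov.loc[:, pa].to_numpy() @ b
            else:
                cross = np.zeros(len(order))
            cov.loc[:, node] = cross
            cov.loc[node, :] = cross
            cov.loc[node, node] = path_var + noise_var
        return cls(graph, dict(coefficients), noise, intercept, seed)


@dataclass
class SimulatedCohort:
    """Simulation output: observed table, optional latent columns, its spec."""

    table: VariableTable
    latent: Optional[pd.DataFrame]
    spec: SEMSpec

    @property
    def n(self) -> int:
        return self.table.n


def simulate(
    spec: SEMSpec,
    n: int,
    seed: Optional[int] = None,
    keep_latent: bool = False,
) -> SimulatedCohort:
    """Draw ``n`` subjects from the SEM.

    Reproducible: the (single-integer) seed expands into one independent
    substream per node, keyed by the node's position in sorted order, so the
    same seed gives the same cohort regardless of construction details.
    Latent columns are withheld from the exported table unless
    ``keep_latent`` — and even then they arrive in a separate frame, never
    in the observed table.
    """
    if n < 1:
        raise ModelConfigError("n must be >= 1")
    use_seed = spec.seed if seed is None else seed
    streams = np.random.SeedSequence(use_seed).spawn(len(spec.graph.nodes))
    rng = {node: np.random.default_rng(ss)
           for node, ss in zip(spec.graph.nodes, streams)}
    cols: dict[str, np.ndarray] = {}
    for node in spec.graph.topological_order():
        val = np.full(n, spec.node_mean[node], dtype=float)
        for p in spec.graph.parents(node):
            val += spec.edge_coefficients[(p, node)] * cols[p]
        val += rng[node].normal(0.0, spec.noise_sd[node], size=n)
        cols[node] = val
    obs = pd.DataFrame({v: cols[v] for v in spec.graph.observed})
    lat = (
        pd.DataFrame({v: cols[v] for v in spec.graph.latent})
        if keep_latent
        else None
    )
    return SimulatedCohort(VariableTable(obs, state="raw"), lat, spec)


def true_total_effect(
    spec: SEMSpec, exposure: str, outcome: str, standardized: bool = False
) -> float:
    """Sum over all directed exposure→outcome paths of edge-coefficient
    products — the population total effect of the SEM.

    Computed in closed form as the off-diagonal entry of ``(I - B')^-1``.
    ``standardized=True`` rescales by the implied SD ratio (effect per SD of
    exposure, in SDs of outcome), which is the quantity a regression on
    z-scored data estimates.  No path means exactly 0.
    """
    nodes, B, _ = spec._matrices()
    idx = {n: i for i, n in enumerate(nodes)}
    total = np.linalg.inv(np.eye(len(nodes)) - B)[idx[outcome], idx[exposure]]
    if exposure == outcome:
        raise ModelConfigError("exposure and outcome must differ")
    if standardized:
        sd = spec.implied_sd()
        total *= sd[exposure] / sd[outcome]
    return float(total)


def true_bivariate_effect(
    spec: SEMSpec, exposure: str, outcome: str, standardized: bool = False
) -> float:
    """Population slope of the single-predictor regression outcome ~ exposure.

    ``cov(x, y) / var(x)`` from the implied covariance; standardized it is
    simply the implied correlation.  Differs from the total effect exactly
    when an open non-causal path links the pair.
    """
    cov = spec.implied_cov()
    slope = cov.loc[outcome, exposure] / cov.loc[exposure, exposure]
    if standardized:
        slope *= np.sqrt(cov.loc[exposure, exposure] / cov.loc[outcome, outcome])
    return float(slope)


def default_sem(seed: int = 0, config: Optional[ModelConfig] = None) -> SEMSpec:
    """The builtin cohort emulator (severity level II calibration)."""
    return cohort_spec("II", seed=seed, config=config)


def cohort_spec(
    level: str, seed: int = 0, config: Optional[ModelConfig] = None
) -> SEMSpec:
    if level not in TABLE_TARGETS:
        raise ModelConfigError(
            f"unknown severity level {level!r}; expected one of "
            f"{sorted(TABLE_TARGETS)}"
        )
    config = config or load_model()
    targets = TABLE_TARGETS[level]
    mean = {**{n: m for n, (m, _) in _LATENT_TARGETS.items()},
            **{n: m for n, (m, _) in targets.items()}}
    sd = {**{n: s for n, (_, s) in _LATENT_TARGETS.items()},
          **{n: s for n, (_, s) in targets.items()}}
    return SEMSpec.from_marginal_targets(
        config.graph, _DEFAULT_COEFFS, mean, sd, seed=seed
    )


def cohort_fixture(level: str, n: int, seed: int = 0) -> SimulatedCohort:
    """Simulate a cohort whose marginals approximate one severity level."""
    return simulate(cohort_spec(level, seed=seed), n)
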