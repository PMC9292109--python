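import numpy as np
import pytest

import cpcausal as cp

#: The eleven conditional independencies the impairment model implies among
#: its observed variables, frozen after confirmation against the brute-force
#: path oracle (small graphs) and an independent d-separation implementation
#: (full model).
NEURO5 = frozenset({"Age", "DMC", "SCALE", "Spasticity", "Strength"})
GMFM_SEP = frozenset(
    {"Age", "AnkleDF", "DMC", "GDI", "HipExt", "KneeExt", "Popliteal",
     "SCALE", "Spasticity", "Strength"}
)
EXPECTED_STATEMENTS = sorted(
    [
        cp.CIStatement("Age", "Strength", frozenset()),
        cp.CIStatement("AnkleDF", "FemRot", NEURO5),
        cp.CIStatement("AnkleDF", "TibRot", NEURO5),
        cp.CIStatement("KneeExt", "FemRot", NEURO5),
        cp.CIStatement("KneeExt", "TibRot", NEURO5),
        cp.CIStatement("Popliteal", "FemRot", NEURO5),
        cp.CIStatement("Popliteal", "TibRot", NEURO5),
        cp.CIStatement("HipExt", "FemRot", NEURO5),
        cp.CIStatement("HipExt", "TibRot", NEURO5),
        cp.CIStatement("TibRot", "GMFM", GMFM_SEP),
        cp.CIStatement("FemRot", "GMFM", GMFM_SEP),
    ],
    key=lambda s: (s.x, s.y),
)


@pytest.fixture(scope="session")
def config() -> cp.ModelConfig:
    return cp.load_model()


@pytest.fixture(scope="session")
def graph(config) -> cp.CausalGraph:
    return config.graph


@pytest.fixture(scope="session")
def sem() -> cp.SEMSpec:
    return cp.default_sem(seed=20)


@pytest.fixture(scope="session")
def cohort20k(sem) -> cp.SimulatedCohort:
    """One moderately large cohort shared by estimation tests."""
    return cp.simulate(sem, 20_000)


@pytest.fixture(scope="session")
def std20k(cohort20k, config) -> cp.VariableTable:
    return cp.standardize_and_orient(cohort20k.table, config)


@pytest.fixture(scope="session")
def big_cohort(sem) -> cp.SimulatedCohort:
    """n=100k draw used for simulator-faithfulness checks."""
    return cp.simulate(sem, 100_000, seed=77)


def random_dag(rng: np.random.Generator, n_nodes: int, p: float = 0.35,
               latent_frac: float = 0.0) -> cp.CausalGraph:
    """A random DAG over nodes n0..n{k-1}; edges follow a random topological
    order so acyclicity holds by construction."""
    names = [f"n{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                edges.append((names[order[i]], names[order[j]]))
    latent = [n for n in names if rng.random() < latent_frac]
    return cp.CausalGraph(names, edges, latent)


def oriented_true_total(spec: cp.SEMSpec, config: cp.ModelConfig,
                        exposure: str) -> float:
    """Closed-form standardized total effect on the *oriented* scale used by
    the estimators (sign-flipped exposures negate the raw-scale truth)."""
    t = cp.true_total_effect(spec, exposure, config.outcome, standardized=True)
    return -t if config.meta(exposure).sign_flip else t


def oriented_true_bivariate(spec: cp.SEMSpec, config: cp.ModelConfig,
                            exposure: str) -> float:
    t = cp.true_bivariate_effect(spec, exposure, config.outcome,
                                 standardized=True)
    return -t if config.meta(exposure).sign_flip else t
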