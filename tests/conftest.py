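import numpy as np
import pytest

import geociaf as g


@pytest.fixture(scope="session")
def small_study():
    """One seeded synthetic study reused across read-only tests."""
    cfg = g.SimulationConfig(n_children=2000, seed=42)
    children, graph, truth = g.simulate_study(cfg)
    return cfg, children, graph, truth


@pytest.fixture(scope="session")
def default_spec():
    return g.ModelSpec.ggamm(
        fixed_terms=[("sex", "male"), ("residence", "rural"),
                     ("wealth", "poorest"), ("year", "2000")],
        smooth_terms=[("age_months", 60), ("maternal_bmi", 20)],
    )


@pytest.fixture(scope="session")
def small_fit(small_study, default_spec):
    _, children, graph, _ = small_study
    design = g.build_design(children, default_spec, graph)
    return g.fit(design, engine="approx", seed=7)


def random_graph(rng: np.random.Generator, n_zones: int, p_edge: float = 0.3):
    """Erdos-Renyi helper for rank/conditioning property tests."""
    edges = [(a, b) for a in range(n_zones) for b in range(a + 1, n_zones)
             if rng.uniform() < p_edge]
    return g.build_adjacency(edges, n_zones=n_zones)
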