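import numpy as np
import pandas as pd
import pytest

from coexnet.synthetic import SyntheticConfig, TraitSpec, simulate_study


def six_module_config(seed: int = 1, **kw) -> SyntheticConfig:
    """Six planted modules (150..40 genes) in a 1000-gene, 90-sample study."""
    defaults = dict(module_sizes=[150, 120, 100, 80, 60, 40], n_genes=1000,
                    n_samples=90, loading_range=(0.6, 0.9), seed=seed)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


def coupled_traits(gammas=(0.5, -0.5, 0.5, -0.5)) -> list[TraitSpec]:
    """Four traits coupled to distinct modules plus six null traits."""
    traits = [TraitSpec(f"T{i + 1}", i, g) for i, g in enumerate(gammas)]
    traits += [TraitSpec(f"N{i + 1}") for i in range(6)]
    return traits


@pytest.fixture(scope="session")
def small_study():
    """A compact study used across tests: 3 modules, 300 genes, 60 samples."""
    traits = [TraitSpec("T1", 0, 0.6), TraitSpec("T2", 1, -0.6),
              TraitSpec("T3", 2, 0.5), TraitSpec("N1"), TraitSpec("N2")]
    cfg = SyntheticConfig(module_sizes=[60, 50, 40], n_genes=300, n_samples=60,
                          loading_range=(0.7, 0.9), traits=traits, seed=42)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def six_module_study():
    return simulate_study(six_module_config(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_expr():
    """Deterministic 6-gene x 8-sample matrix with two correlated pairs."""
    rng = np.random.default_rng(7)
    base = rng.standard_normal((6, 8))
    base[1] = base[0] * 0.9 + 0.1 * rng.standard_normal(8)
    base[3] = -base[2]
    return pd.DataFrame(base, index=[f"G{i}" for i in range(6)],
                        columns=[f"S{j}" for j in range(8)])
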