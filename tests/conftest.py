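import numpy as np
import pytest

from pigquant.simdata import SimulationConfig, TraitSimSpec, simulate_herd


@pytest.fixture(scope="session")
def small_herd():
    """~300 phenotyped pigs, one Gaussian trait with h2 = 0.5."""
    spec = TraitSimSpec(
        name="t", mu=1.0, sigma2_a=0.5, sigma2_le=0.1, sigma2_e=0.4,
        fixed_effects={"sex": (0.0, 0.2)},
    )
    cfg = SimulationConfig(n_sires=10, n_dams=40, litter_size_mean=7.4, seed=42,
                           traits={"t": spec})
    return simulate_herd(cfg)


def random_pedigree_records(n, seed, p_known=0.7):
    """Sequentially generated random valid pedigree (parents precede children)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        sire = dam = ""
        if i >= 2 and rng.random() < p_known:
            sire = f"a{rng.integers(i)}"
            dam = f"a{rng.integers(i)}"
            if sire == dam:
                dam = ""
        records.append((f"a{i}", sire, dam))
    return records
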