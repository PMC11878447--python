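import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ringeralign.ringer_io import AngleGrid, ChiProfile, ResidueId, StructureProfileSet
from ringeralign.synthetic import default_pair_spec, generate_pair

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_profile_set(rng: np.random.Generator, label: str,
                       n_residues: int = 5, n_samples: int = 72,
                       chain: str = "A") -> StructureProfileSet:
    """Random but structurally valid profile set for fuzz tests."""
    from ringeralign.restypes import ROTAMERIC, chi_count

    grid = AngleGrid(n_samples=n_samples)
    pset = StructureProfileSet(model_label=label, grid=grid)
    start = int(rng.integers(1, 50))
    for k in range(n_residues):
        name = str(rng.choice(ROTAMERIC))
        rid = ResidueId(chain_id=chain, res_num=start + k, res_name=name)
        for chi in range(1, chi_count(name) + 1):
            sig = np.round(rng.normal(0.5, 0.4, n_samples), 6)
            pset.add(rid, ChiProfile(residue=rid, chi_index=chi, sigmas=sig))
    return pset


@pytest.fixture(scope="session")
def small_pair(tmp_path_factory):
    """Small synthetic homolog pair shared across tests (seed-fixed)."""
    spec = default_pair_spec(seed=7, n_residues=15, renumber_offset=11,
                             n_extra_rotamers=3)
    out = tmp_path_factory.mktemp("fixture")
    return generate_pair(spec, out)
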