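import pytest

from migranet.datamodel import DNAProfile, HaplotypeSet
from migranet.simulate import SimConfig, simulate_island_model


@pytest.fixture
def toy_profiles():
    """Six hand-built profiles over two locations / management units."""
    mk = lambda sid, loc, mu, hap, g: DNAProfile(
        sample_id=sid, location=loc, habitat="calving", management_unit=mu,
        sex="F", haplotype=hap, genotype=g,
    )
    return [
        mk("a1", "WA", "SWA", "HapA", {"L1": (100, 102), "L2": (200, 200)}),
        mk("a2", "WA", "SWA", "HapA", {"L1": (100, 100), "L2": (200, 202)}),
        mk("a3", "WA", "SWA", "HapB", {"L1": (102, 102), "L2": (202, 202)}),
        mk("b1", "VIC", "SEA", "HapB", {"L1": (104, 104), "L2": (204, 204)}),
        mk("b2", "VIC", "SEA", "HapC", {"L1": (104, 106), "L2": (204, 206)}),
        mk("b3", "VIC", "SEA", "HapC", {"L1": (106, 106), "L2": (206, 206)}),
    ]


@pytest.fixture
def toy_hapset():
    base = "ACGT" * 5
    return HaplotypeSet(
        {
            "HapA": base,
            "HapB": "T" + base[1:],  # 1 difference from HapA
            "HapC": "TG" + base[2:],  # 2 from HapA, 1 from HapB
        }
    )


@pytest.fixture(scope="session")
def island_sim_f10():
    """Two demes of 50, 100 loci, target F_ST = 0.10 (shared across tests)."""
    cfg = SimConfig(n_regions=2, n_per_region=50, n_loci=100, target_fst=0.10, seed=2024)
    profiles, truth = simulate_island_model(cfg)
    return cfg, profiles, truth


@pytest.fixture(scope="session")
def island_sim_null():
    cfg = SimConfig(n_regions=2, n_per_region=50, n_loci=100, target_fst=0.0, seed=2025)
    profiles, truth = simulate_island_model(cfg)
    return cfg, profiles, truth
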