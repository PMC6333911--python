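import numpy as np
import pytest

from breedsim import (FounderConfig, build_genome_map,
                      simulate_founder_population)
from breedsim.scheduler import Scenario
from breedsim.config import scenario_from_dict


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_map():
    """1 chromosome, 1 Morgan, 100 loci (every 10th a QTL), 10 IBD loci."""
    return build_genome_map(1, 1.0, 100, qtl_every_n=10, n_ibd=10)


@pytest.fixture(scope="session")
def small_pool(small_map):
    rng = np.random.default_rng(7)
    eff = rng.exponential(1.0, small_map.n_qtl) * np.where(
        rng.random(small_map.n_qtl) < 0.9, -1, 1)
    cfg = FounderConfig(n_pat=20, n_mat=20, ng_founder=60, mutation_rate=5e-3)
    return simulate_founder_population(cfg, small_map, eff, rng)


def mini_scenario(name="mini", gs=False, speed=False, horizon=8,
                  burn_in_switch=None) -> Scenario:
    """A fast, structurally complete 4-generation line-breeding plan used by
    the scheduler/reporting tests: cross 6 parents, self to F2, family
    selection at F2, line stages at F3/F4."""
    sel3 = {"unit": "entire_family", "family": "line", "trait": "YP",
            "n_selected": 3, "criterion": "phenotype"}
    if gs:
        sel3 = dict(sel3, criterion="gblup", burn_in_criterion="phenotype",
                    index_trait="YP")
    calendar = [0, 0, 1, 2] if speed else [0, 1, 2, 3]
    data = {
        "name": name,
        "n_replicates": 2,
        "genome": {"n_chromosomes": 2, "chrom_length": 1.0, "n_loci": 60,
                   "qtl_every_n": 5, "n_ibd": 6},
        "founder": {"n_pat": 8, "n_mat": 8, "ng_founder": 25,
                    "mutation_rate": 0.01},
        "traits": {
            "names": ["BVP", "YP"],
            "sigma_g2": [1.0, 1.0],
            "correlations": [[1.0, 0.2], [0.2, 1.0]],
            "noise": {"BVP": {"h2": 0.25},
                      "YP": {"h2_plot": 0.3, "ns": 4, "homozygosity": 0.75}},
        },
        "plan": {
            "last_generation": 4,
            "horizon": horizon,
            "calendar": calendar,
            "burn_in_switch": burn_in_switch,
            "crossing": {"n_crosses": 5, "max_uses": 3, "n_seeds_per_cross": 1},
            "parent_source": {"n_parents": 6,
                              "founder_cycles": 4 if speed else 4,
                              "store_generations": [3],
                              "policy": "uniform", "base_inbred": True},
            "stages": [
                {"generation": 1,
                 "propagation": {"type": "selfing", "n_seeds": 8, "per": "plant"}},
                {"generation": 2,
                 "phenotyping": [{"trait": "BVP", "level": "plant"}],
                 "selection": {"unit": "within_family", "family": "f1",
                               "criterion": "phenotype", "trait": "BVP",
                               "n_selected": 2},
                 "propagation": {"type": "selfing", "n_seeds": 4, "per": "plant"},
                 "start_lines": True, "genotype": gs},
                {"generation": 3,
                 "phenotyping": [{"trait": "YP", "level": "family",
                                  "family": "line", "n_plots": 2}],
                 "selection": sel3,
                 "propagation": {"type": "selfing", "n_seeds": 6, "per": "family"},
                 "store_germplasm": True},
            ],
        },
    }
    if burn_in_switch is None:
        del data["plan"]["burn_in_switch"]
    return scenario_from_dict(data)


@pytest.fixture
def mini():
    return mini_scenario()
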