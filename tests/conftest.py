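import numpy as np
import pytest

from autozyg.simdata import SimConfig, gene_drop, simulate_pedigree


@pytest.fixture(scope="session")
def fullsib_cohort():
    """30 independent full-sib matings, 5 chromosomes x 1000 SNPs, no noise.

    Session-scoped because several modules check their estimator against
    the same ground truth.
    """
    design = [{"kind": "full_sib", "n_offspring": 4} for _ in range(30)]
    cfg = SimConfig(mating_design=design, n_chromosomes=5,
                    n_snps_per_chrom=1000, seed=11)
    ped = simulate_pedigree(cfg)
    G, M, truth = gene_drop(ped, cfg)
    offspring = [i for i in G.individual_ids if "_O" in i]
    return cfg, ped, G, M, truth, offspring


@pytest.fixture(scope="session")
def mixed_cohort():
    """Full-sib units on top of a small closed population: spread of true
    autozygosity from 0 to ~0.3 for rank-recovery checks."""
    design = ([{"kind": "full_sib", "n_offspring": 3} for _ in range(10)]
              + [{"kind": "closed_population", "n_founders": 10,
                  "n_generations": 8, "n_per_generation": 12}])
    cfg = SimConfig(mating_design=design, n_chromosomes=4,
                    n_snps_per_chrom=1000, seed=23,
                    genotyping_error=0.001, missing_rate=0.005)
    ped = simulate_pedigree(cfg)
    G, M, truth = gene_drop(ped, cfg)
    return cfg, ped, G, M, truth


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
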