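"""Shared fixtures: small genomes, a reusable strong-interaction ensemble."""

import numpy as np
import pytest

import oridyn as od


@pytest.fixture(scope="session")
def strong_interaction_ensemble():
    """Ensemble at the strong-interaction parameter point: one 3000-kb
    chromosome, periodic origins at rho0 = 0.28 /kb, v = 0.6 kb/min,
    kon = 6e-3 /min, NDT = 165, tau = 3 min (the bell-shaped regime).

    Session-scoped because several shape/coincidence checks share it.
    """
    rng = np.random.default_rng(2024)
    genome = od.periodic_genome(3000.0, 0.28, rng)
    params = od.SimParams(genome=genome, v=0.6, kon=6e-3, ndt=165, tau_load=3.0)
    return od.run_ensemble(params, n_runs=100, master_seed=42, bin_width=0.5)


@pytest.fixture()
def yeast_like_origin_file(tmp_path):
    """Synthetic OriDB-style origin map: 16 chromosomes with real
    S. cerevisiae lengths, 410 Confirmed + 216 Likely + 203 Dubious
    origins at synthetic (uniform random) positions.
    """
    rng = np.random.default_rng(77)
    path = tmp_path / "yeast_synthetic_origins.tsv"
    od.generate_fixture_origin_file(
        path, od.YEAST_CHROM_LENGTHS_KB,
        {"Confirmed": 410, "Likely": 216, "Dubious": 203}, rng)
    return path
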