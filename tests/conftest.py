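import numpy as np
import pytest

from radfp import GenotypeMatrix, SimulationConfig, simulate_genotypes


def make_matrix(rows: list[list[str]], accession_ids=None, marker_ids=None,
                positions=None) -> GenotypeMatrix:
    """Small literal genotype matrix for hand-computed cases."""
    n, m = len(rows), len(rows[0])
    return GenotypeMatrix(
        accession_ids or [f"a{i}" for i in range(n)],
        marker_ids or [f"m{j}" for j in range(m)],
        positions or [("Chr1", 1000 * (j + 1)) for j in range(m)],
        np.array(rows, dtype="<U2"),
    )


@pytest.fixture(scope="session")
def panel_scale():
    """A study-scale synthetic panel: 356 accessions x 32 markers, two admixed
    subpopulations, one planted 7-member duplicate group."""
    return simulate_genotypes(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def random_matrix():
    """A mid-size random panel without duplicate structure, for oracles."""
    cfg = SimulationConfig(n_accessions=40, n_markers=12, n_duplicate_groups=0,
                           missing_rate_range=(0.0, 0.2), seed=9)
    matrix, _ = simulate_genotypes(cfg)
    return matrix
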