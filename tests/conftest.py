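import numpy as np
import pytest

from bafscreen import (
    MixtureSpec,
    simulate_lineage_panel,
    simulate_panel,
    simulate_read_counts,
    simulate_reference,
)
from bafscreen.simulate import most_divergent_pair


@pytest.fixture(scope="session")
def small_reference():
    return simulate_reference(n_chromosomes=2, chrom_length=25_000, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_reference):
    return simulate_panel(small_reference, n_strains=6, divergence_target=0.005, seed=11)


@pytest.fixture(scope="session")
def lineage_panel(small_reference):
    return simulate_lineage_panel(
        small_reference, n_lineages=6, strains_per_lineage=2,
        divergence_target=0.005, seed=11,
    )


@pytest.fixture(scope="session")
def big_reference():
    # large enough for ~20k SNP sites at 0.5% divergence
    return simulate_reference(n_chromosomes=2, chrom_length=2_000_000, seed=17)


@pytest.fixture(scope="session")
def big_panel(big_reference):
    return simulate_panel(big_reference, n_strains=4, divergence_target=0.005, seed=17)


def contaminated_records(panel, c, seed, depth=80.0, **kwargs):
    """Read counts for the panel's most divergent (recipient, contaminant) pair."""
    a, b = most_divergent_pair(panel)
    rec, con = panel.strains[a], panel.strains[b]
    spec = MixtureSpec(a, b, c, depth, seed)
    return simulate_read_counts(rec, con if c > 0 else None, spec, **kwargs)
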