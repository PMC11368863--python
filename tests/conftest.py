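import pandas as pd
import pytest

from copath import (
    SimulationConfig,
    enumerate_events,
    estimate_dispersion,
    filter_unexpressed,
    quantile_normalize,
    select_ligand_paths,
    simulate_counts,
)
from copath.de import test_all_contrasts


@pytest.fixture(scope="session")
def default_catalog():
    return select_ligand_paths(enumerate_events())


@pytest.fixture(scope="session")
def planted_run():
    """End-to-end run on the default planted design with baseline means >= 100.

    Shared across tests: simulation -> filter -> quantile normalization ->
    dispersion estimation -> all three contrasts.
    """
    config = SimulationConfig(baseline_mean_range=(100.0, 2000.0), seed=7)
    counts, design, truth = simulate_counts(config)
    normalized = quantile_normalize(filter_unexpressed(counts))
    dispersions = estimate_dispersion(normalized, design)
    de = test_all_contrasts(normalized, design, dispersions)
    return {
        "config": config,
        "counts": counts,
        "design": design,
        "truth": truth,
        "normalized": normalized,
        "dispersions": dispersions,
        "de": de,
    }


@pytest.fixture(scope="session")
def null_run():
    """Null simulation (no planted effects) through normalization and DE."""
    config = SimulationConfig(planted_paths=(), seed=11)
    counts, design, truth = simulate_counts(config)
    normalized = quantile_normalize(filter_unexpressed(counts))
    dispersions = estimate_dispersion(normalized, design)
    de = test_all_contrasts(normalized, design, dispersions)
    return {
        "config": config,
        "counts": counts,
        "design": design,
        "truth": truth,
        "normalized": normalized,
        "de": de,
    }
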