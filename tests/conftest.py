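import numpy as np
import pytest

from ploidypath import (AnalysisDataset, LineageRecord, SimulationParams,
                        filter_lineages, simulate_dataset, tree_from_string)


def make_record(lineage_id="L1", archipelago="NZ", n_native=5, n_endemic=3,
                n_ploidy_levels=2, monophyletic=True, ploidy_change=False,
                stem_age=10.0, stem_age_sd=2.0, crown_age=None,
                source_pool=40, prop=0.8, dated=True, counted=True,
                **kw) -> LineageRecord:
    return LineageRecord(
        lineage_id=lineage_id, genus=f"G{lineage_id}",
        archipelago=archipelago, n_native=n_native, n_endemic=n_endemic,
        n_ploidy_levels=n_ploidy_levels,
        monophyletic_on_island=monophyletic,
        ploidy_change_vs_sister=ploidy_change,
        stem_age=stem_age, stem_age_sd=stem_age_sd, crown_age=crown_age,
        source_pool_size=source_pool, prop_chrom_counted=prop,
        has_dated_phylogeny=dated, has_chromosome_count=counted, **kw)


@pytest.fixture
def toy_records():
    """Five records with known inclusion-flag combinations."""
    return [
        make_record("A1", "NZ"),                          # retained
        make_record("A2", "CI", n_native=1, n_endemic=1),  # crit 1 fails
        make_record("A3", "HI", dated=False),              # crit 2 fails
        make_record("A4", "JF", counted=False,
                    n_ploidy_levels=0, prop=0.0),          # crit 3 fails
        make_record("A5", "GI", n_native=1, n_endemic=0,
                    dated=False, counted=False,
                    n_ploidy_levels=0, prop=0.0),          # all fail
    ]


@pytest.fixture
def toy_dataset():
    recs = [
        make_record("L1", "NZ", stem_age=12.0, stem_age_sd=4.0),
        make_record("L2", "NZ", stem_age=5.0, stem_age_sd=1.0,
                    n_endemic=4, n_ploidy_levels=3),
        make_record("L3", "CI", stem_age=8.0, stem_age_sd=2.0,
                    n_endemic=2, n_ploidy_levels=1, ploidy_change=True),
        make_record("L4", "CI", stem_age=3.0, stem_age_sd=0.5,
                    n_endemic=7, n_ploidy_levels=2, monophyletic=False),
    ]
    return filter_lineages(recs)


@pytest.fixture
def toy_tree():
    return tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated study, shared across tests."""
    dataset, tree, truth = simulate_dataset(SimulationParams(seed=42))
    return dataset, tree, truth


@pytest.fixture(scope="session")
def latent_sim():
    """Continuous-response (latent) simulation for calibration checks."""
    params = SimulationParams(seed=43, round_counts=False)
    dataset, tree, truth = simulate_dataset(params)
    return dataset, tree, truth


def random_gls_instance(rng, n, p=2):
    """A random small weighted-PGLS problem on a random coalescent-ish tree."""
    from ploidypath import brownian_cov, simulate_tree
    tree = simulate_tree(n, 1.0, seed=int(rng.integers(2**31 - 1)))
    cov = brownian_cov(tree)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) \
        if p > 1 else np.ones((n, 1))
    y = rng.normal(size=n)
    w = rng.uniform(0.2, 3.0, size=n)
    return X, y, cov.R, w
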