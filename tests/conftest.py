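import pytest

from retroforge.discovery import discover
from retroforge.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_ds():
    """A compact dataset: 3 chromosomes x 120 kb, 8 genes, 6 retro events."""
    cfg = SimulationConfig(
        seed=1,
        n_genes=8,
        n_retro_events=6,
        n_chromosomes=3,
        chromosome_length=120_000,
        n_ests=40,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_catalogue(small_ds):
    return discover(small_ds.genome, small_ds.models, small_ds.proteins)


@pytest.fixture(scope="session")
def default_ds():
    """The standard study-scale dataset: ~2 Mb, 40 genes, 50 events."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_catalogue(default_ds):
    ds = default_ds
    return discover(ds.genome, ds.models, ds.proteins)


def match_truth(record, truth_events):
    """The truth event whose locus reciprocally overlaps a called record."""
    for t in truth_events:
        if (
            t.chrom == record.chrom
            and min(t.end, record.end) - max(t.start, record.start)
            > 0.5 * (t.end - t.start)
        ):
            return t
    return None
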