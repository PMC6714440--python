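import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def or_simulation():
    """300 OR-like genes spanning all lesion types, with truth labels."""
    from raptorsig import simulate

    genes, scaffolds, truth = simulate.gen_or_genes(
        n_intact=120, n_partial=90, n_pseudo=90, aa_length=310, seed=11
    )
    return genes, scaffolds, truth


@pytest.fixture(scope="session")
def hcr_scan_default():
    """The default synthetic scan: 200 x 100 kb windows, background 5e-3,
    five planted windows at multiplier 0.05, seed 1."""
    from raptorsig import hcr, simulate

    cfg = simulate.SimConfig(seed=1)
    positions, truth = simulate.gen_order_differences(cfg)
    windows, regions = hcr.scan_hcrs(positions, {"sim1": cfg.genome_length})
    return cfg, truth, windows, regions
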