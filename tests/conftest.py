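import numpy as np
import pytest

from repquant.synthetic_data import (
    DesignMatrixSpec,
    SubfamilySpec,
    build_genome,
    simulate_sample,
)


def tiny_specs(groups=3):
    """Six subfamilies over four family types, incl. a sibling pair whose
    near-identical consensi force cross-subfamily multi-mapping."""
    w = lambda *vals: tuple(vals[:groups])
    return [
        SubfamilySpec("AlphaL1_a", "L1", "LINE", 300, 4, 0.08, w(2.0, 2.0, 2.0)),
        SubfamilySpec(
            "AlphaL1_b", "L1", "LINE", 300, 3, 0.01, w(1.0, 1.0, 1.0),
            parent="AlphaL1_a", parent_divergence=0.01,
        ),
        SubfamilySpec("BetaSINE", "B1", "SINE", 120, 6, 0.06, w(3.0, 3.0, 3.0)),
        SubfamilySpec("GammaLTR", "ERVK", "LTR", 250, 3, 0.07, w(1.5, 1.5, 1.5)),
        SubfamilySpec("DeltaSat", "Satellite", "Satellite", 200, 4, 0.02,
                      w(1.0, 1.0, 4.0)),
        SubfamilySpec("EpsSINE", "B2", "SINE", 130, 5, 0.05, w(0.5, 0.5, 0.5)),
    ]


def tiny_design(seed=0, reads=3000, dispersion=0.05, groups=("young", "mid", "old")):
    return DesignMatrixSpec(
        group_labels=tuple(groups),
        replicates=3,
        dispersion=dispersion,
        background_fraction=0.3,
        reads_per_sample=reads,
        read_length=50,
        error_rate=0.005,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_world():
    """A 30 kb genome with 6 planted subfamilies and its catalog/truth."""
    design = tiny_design()
    genome, catalog, truth = build_genome(tiny_specs(), 30_000, design.seed,
                                          design=design)
    return genome, catalog, truth, design


@pytest.fixture(scope="session")
def tiny_sample(tiny_world):
    """One simulated sample (reads + per-read truth) from tiny_world."""
    genome, catalog, truth, design = tiny_world
    reads, read_truth = simulate_sample(
        genome, catalog, truth, design, "old", 1
    )
    return reads, read_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
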