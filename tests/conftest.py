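import numpy as np
import pytest

import kairoscan as ks


def tiny_config(seed=0, **overrides):
    """A small, fast simulation config shared across tests."""
    defaults = dict(
        seed=seed,
        n_chroms=1,
        chrom_length_bp=400_000,
        n_genes=80,
        gene_length_range=(800, 1500),
        bin_size_bp=200,
        pathways=[
            ks.PathwaySpec(
                "PWY-CAMALEXIN", "specialized", 10, {"H3K27me3": 3.0, "H3K18ac": 3.0}
            ),
            ks.PathwaySpec("PWY-NULL-1", "specialized", 10),
            ks.PathwaySpec("PWY-NULL-2", "amino-acid", 10),
        ],
        bivalent_set=ks.BivalentSpec(size=10),
    )
    defaults.update(overrides)
    return ks.SimConfig(**defaults)


def minimal_assay_kwargs():
    """Trim the qPCR/metabolite schedules to a single planted context."""
    return dict(
        expression_fc={("TGT", "Col-0", 30): 1.0},
        chip_effects={},
        seqchip_recovery={},
        conc_fc={("Col-0", 30): 1.0},
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    return ks.simulate_all(tiny_config(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
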