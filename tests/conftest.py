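import numpy as np
import pytest

from l1prom.synthetic_data import SimConfig, generate_genome, generate_templates


@pytest.fixture(scope="session")
def templates():
    rng = np.random.default_rng(11)
    return generate_templates(SimConfig(seed=11), rng)


@pytest.fixture(scope="session")
def template_seqs(templates):
    return {name: t.monomer_seq for name, t in templates.items()}


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but complete synthetic genome reused across read-only tests."""
    cfg = SimConfig(
        seed=7, n_chroms=4, chrom_len=250_000, n_l1=30,
        flank_window=40_000, island_fraction=0.2, mutated_yy1_fraction=0.2,
    )
    out = tmp_path_factory.mktemp("small_sim")
    return cfg, generate_genome(cfg, out)
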