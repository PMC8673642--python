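import numpy as np
import pandas as pd
import pytest

from nanogebv import simdata
from nanogebv.core import validate_loci


@pytest.fixture()
def toy_loci():
    """Five target SNPs on one chromosome with known alt frequencies."""
    return validate_loci(
        pd.DataFrame(
            {
                "locus_id": [f"s{i}" for i in range(1, 6)],
                "chrom": "chr1",
                "pos": [100, 200, 300, 400, 500],
                "ref": ["A", "C", "G", "T", "A"],
                "alt": ["G", "T", "A", "C", "C"],
                "alt_freq": [0.0, 0.25, 0.5, 0.75, 1.0],
            }
        )
    )


@pytest.fixture()
def small_cfg():
    """Desk-scale study conditions for fast pipeline tests."""
    return simdata.SimConfig(
        n_markers=300, n_individuals=40, n_panel_haplotypes=24, seed=123
    )


@pytest.fixture()
def small_world(small_cfg):
    """Panel, truth, effects and full-coverage counts for one small cohort."""
    panel = simdata.simulate_panel(small_cfg)
    truth = simdata.sample_individuals(
        panel, small_cfg.n_individuals, small_cfg.seed, small_cfg.switch_rate
    )
    effects = simdata.simulate_effects(small_cfg)
    counts = simdata.simulate_pileup(truth, small_cfg)
    return small_cfg, panel, truth, effects, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
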