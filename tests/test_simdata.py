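"""Statistical and determinism properties of the synthetic-data generator."""

import numpy as np
import pytest

from nanogebv import simdata
from nanogebv.errors import ConfigError
from nanogebv.gebv import effect_share, trait_columns


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_markers": 0},
        {"n_individuals": -1},
        {"af_low": 0.0},
        {"af_low": 0.6, "af_high": 0.4},
        {"switch_rate": 1.5},
        {"coverage": -1.0},
        {"base_quality": 0.0},
        {"effect_sd": 0.0},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        simdata.SimConfig(**kwargs)


def test_unknown_config_key_rejected():
    with pytest.raises(ConfigError, match="unknown"):
        simdata.SimConfig.from_dict({"n_markers": 10, "coverage_x": 2})


def test_same_seed_gives_bit_identical_outputs(small_cfg):
    a = simdata.simulate_panel(small_cfg)
    b = simdata.simulate_panel(small_cfg)
    assert np.array_equal(a.alleles, b.alleles)
    ta = simdata.sample_individuals(a, 10, 7)
    tb = simdata.sample_individuals(b, 10, 7)
    assert np.array_equal(ta.dosages, tb.dosages)
    assert simdata.simulate_effects(small_cfg).equals(simdata.simulate_effects(small_cfg))
    ca = simdata.simulate_pileup(ta, small_cfg)
    cb = simdata.simulate_pileup(tb, small_cfg)
    assert np.array_equal(ca.ref, cb.ref) and np.array_equal(ca.alt, cb.alt)


def test_zero_switch_rate_copies_founders_exactly():
    cfg = simdata.SimConfig(n_markers=150, n_founders=5, switch_rate=0.0, seed=1)
    panel = simdata.simulate_panel(cfg)
    rng = simdata.substream(cfg.seed, "panel")
    p = rng.uniform(cfg.af_low, cfg.af_high, size=cfg.n_markers)
    founders = (rng.random((cfg.n_founders, cfg.n_markers)) < p).astype(np.int8)
    for hap in panel.alleles:
        assert any(np.array_equal(hap, f) for f in founders)


def _adjacent_r2(switch_rate: float, seed: int, m: int = 300) -> float:
    cfg = simdata.SimConfig(
        n_markers=m, switch_rate=switch_rate, seed=seed,
        n_panel_haplotypes=40, n_founders=40,
    )
    a = simdata.simulate_panel(cfg).alleles.astype(float)
    vals = []
    for j in range(m - 1):
        x, y = a[:, j], a[:, j + 1]
        if x.std() > 0 and y.std() > 0:
            vals.append(np.corrcoef(x, y)[0, 1] ** 2)
    return float(np.mean(vals))


def test_linkage_decays_with_switch_rate():
    """Adjacent-marker r^2 must be strictly larger without template switching."""
    r2_tight = np.mean([_adjacent_r2(0.0, s) for s in range(10)])
    r2_loose = np.mean([_adjacent_r2(1.0, s) for s in range(10)])
    assert r2_tight > r2_loose


def test_monomorphic_panel_gives_constant_dosages():
    loci = simdata._make_loci(20)
    for allele, want in ((0, 0), (1, 2)):
        panel = simdata.HaplotypePanel(
            alleles=np.full((1, 20), allele, dtype=np.int8), loci=loci
        )
        truth = simdata.sample_individuals(panel, 5, seed=0)
        assert (truth.dosages == want).all()


def test_mean_dosage_tracks_panel_frequency():
    cfg = simdata.SimConfig(n_markers=120, seed=5)
    panel = simdata.simulate_panel(cfg)
    truth = simdata.sample_individuals(panel, 1500, seed=5, switch_rate=0.5)
    p = panel.alt_freq()
    se = np.sqrt(np.maximum(2 * p * (1 - p), 1e-9) / 1500) * 2  # binomial SE of mean
    assert (np.abs(truth.dosages.mean(axis=0) - 2 * p) <= 3 * se + 3e-3).all()


def test_effect_shares_normalize_and_stay_polygenic():
    """Per-marker shares of summed |effect| must total 1 and stay tiny."""
    worst = 0.0
    m = 2000
    for seed in range(10):
        eff = simdata.simulate_effects(simdata.SimConfig(n_markers=m, seed=seed))
        shares = effect_share(eff)
        for t in trait_columns(eff):
            assert np.isclose(np.abs(shares[t]).sum(), 1.0)
            worst = max(worst, np.abs(shares[t]).max())
    assert worst < 50 / m


def test_effects_scale_linearly_to_zero():
    """Effects are linear in effect_sd, so the sd -> 0 limit is all-zero."""
    base = simdata.simulate_effects(simdata.SimConfig(seed=3, n_markers=100))
    tiny = simdata.simulate_effects(
        simdata.SimConfig(seed=3, n_markers=100, effect_sd=1e-12)
    )
    for t in trait_columns(base):
        assert np.abs(tiny[t]).max() < 1e-9
        assert np.allclose(tiny[t] / 1e-12, base[t] / 1e-3)


def test_iid_effects_are_plain_normal_draws():
    cfg = simdata.SimConfig(n_markers=5000, seed=9, n_traits=1)
    eff = simdata.simulate_effects(cfg, method="iid")
    e = eff["trait1"].to_numpy()
    assert abs(e.mean()) < 4 * cfg.effect_sd / np.sqrt(len(e))
    assert np.isclose(e.std(), cfg.effect_sd, rtol=0.05)


def test_realized_depth_matches_target_coverage(small_world):
    cfg, _, truth, _, counts = small_world
    total = counts.depth + counts.other
    se = np.sqrt(cfg.coverage / total.size)
    assert abs(total.mean() - cfg.coverage) <= 3 * se


def test_zero_coverage_yields_all_missing_depth(small_world):
    cfg, _, truth, _, _ = small_world
    c0 = simdata.simulate_pileup(
        truth, simdata.SimConfig(n_markers=cfg.n_markers, coverage=0.0, seed=1)
    )
    assert (c0.depth == 0).all()


def test_infinite_quality_is_error_free(small_world):
    cfg, _, truth, _, _ = small_world
    clean = simdata.simulate_pileup(
        truth,
        simdata.SimConfig(n_markers=cfg.n_markers, coverage=8.0, base_quality=2000, seed=2),
    )
    hom_ref = truth.dosages == 0
    hom_alt = truth.dosages == 2
    assert clean.alt[hom_ref].sum() == 0
    assert clean.ref[hom_alt].sum() == 0


def test_error_read_fraction_matches_phred_rate():
    """At Q=20 about 1% of reads from homozygous loci are the wrong allele."""
    cfg = simdata.SimConfig(
        n_markers=150, n_individuals=60, coverage=20.0, base_quality=20.0, seed=4
    )
    panel = simdata.simulate_panel(cfg)
    truth = simdata.sample_individuals(panel, cfg.n_individuals, cfg.seed, cfg.switch_rate)
    counts = simdata.simulate_pileup(truth, cfg)
    hom_ref = truth.dosages == 0
    hom_alt = truth.dosages == 2
    errors = counts.alt[hom_ref].sum() + counts.ref[hom_alt].sum()
    total = counts.depth[hom_ref].sum() + counts.depth[hom_alt].sum()
    assert total > 1e5
    e = 0.01
    half_width = 2.576 * np.sqrt(e * (1 - e) / total)  # 99% binomial interval
    assert abs(errors / total - e) <= half_width


def test_other_allele_routing():
    cfg = simdata.SimConfig(n_markers=100, n_individuals=50, coverage=20.0,
                            base_quality=10.0, seed=6)
    panel = simdata.simulate_panel(cfg)
    truth = simdata.sample_individuals(panel, cfg.n_individuals, cfg.seed, cfg.switch_rate)
    with_other = simdata.simulate_pileup(truth, cfg, other_rate=1.0)
    assert with_other.other.sum() > 0
    no_other = simdata.simulate_pileup(truth, cfg)
    assert no_other.other.sum() == 0


def test_panel_vcf_roundtrip(tmp_path, small_cfg):
    from nanogebv.core import read_panel_vcf

    panel = simdata.simulate_panel(small_cfg)
    path = tmp_path / "panel.vcf"
    simdata.write_panel_vcf(panel, path)
    alleles, loci = read_panel_vcf(path)
    assert np.array_equal(alleles, panel.alleles)
    assert np.allclose(loci["alt_freq"], panel.alt_freq())
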