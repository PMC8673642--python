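"""Synthetic inputs for the low-coverage genotyping-to-prediction pipeline.

The generator emulates the statistical structure the downstream analysis
relies on, at desk scale:

* a phased reference haplotype panel with linkage disequilibrium, built as
  founder mosaics (each panel haplotype copies one of a few founder
  haplotypes, switching template between adjacent markers with a small
  probability, so nearby markers stay correlated);
* diploid study individuals drawn from the panel by the same mosaic
  process (two haplotypes each, dosage = h1 + h2);
* highly polygenic marker effects, produced the way real SNP-BLUP effect
  tables are: back-solved by ridge regression from the breeding values of
  a reference cohort drawn from the same panel (a plain i.i.d. Gaussian
  draw is available as an option). Back-solved effects lie in the row
  space of the reference genotype matrix, which is what makes
  between-individual GEBV variance large relative to per-locus noise —
  the regime in which mean-imputation visibly shrinks prediction
  variance;
* low-coverage sequencing pileups: per-locus read depth is Poisson at the
  target mean coverage, and each read reports the wrong allele with the
  Phred-scaled error probability 10^(-Q/10).

All operations are deterministic given ``SimConfig.seed``: the master seed
spawns one named substream per operation, so regenerating any single
artifact does not disturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, AlleleCountMatrix, validate_loci
from .errors import ConfigError

__all__ = [
    "SimConfig",
    "HaplotypePanel",
    "TrueGenotypes",
    "simulate_panel",
    "sample_individuals",
    "simulate_effects",
    "simulate_pileup",
]

# Substream labels: stable integers mixed into the master seed.
_STREAMS = {"panel": 0, "individuals": 1, "effects": 2, "pileup": 3, "reference": 4}


def substream(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    """Independent, documented RNG substream derived from the master seed."""
    if name not in _STREAMS:
        raise ConfigError(f"unknown RNG substream {name!r}")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name], extra))
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults mirror a low-coverage Nanopore genotyping study on cattle:
    full coverage 6.3x with per-base quality Q ~ 20.5, thinned downstream
    to 4x / 2x / 1x / 0.5x; four polygenic traits; a phased reference
    panel an order of magnitude larger than the study cohort.

    Parameters
    ----------
    n_markers
        Number of target SNP loci (markers on the evaluation array).
    n_panel_haplotypes
        Haplotypes in the phased reference panel.
    n_individuals
        Diploid study individuals.
    n_founders
        Founder haplotypes behind the mosaic panel; fewer founders means
        stronger haplotype sharing.
    switch_rate
        Probability per adjacent-marker interval of switching founder
        template; smaller values give longer-range linkage disequilibrium.
    af_low, af_high
        Bounds of the uniform founder alternate-allele frequency.
    effect_sd
        Standard deviation of per-marker effects (per alt-allele copy,
        trait units).
    n_traits
        Number of traits with independent effect vectors.
    coverage
        Mean sequencing depth per locus (x).
    base_quality
        Phred-scaled per-base quality Q; error rate is 10^(-Q/10).
    n_reference
        Individuals in the reference cohort whose breeding values are
        back-solved into marker effects.
    ridge
        Ridge regularisation of the effect back-solve, as a fraction of
        the mean diagonal of the reference genomic relationship matrix.
    seed
        Master RNG seed.
    """

    n_markers: int = 2000
    n_panel_haplotypes: int = 40
    n_individuals: int = 200
    n_founders: int = 8
    switch_rate: float = 0.005
    af_low: float = 0.05
    af_high: float = 0.95
    effect_sd: float = 0.001
    n_traits: int = 4
    coverage: float = 6.3
    base_quality: float = 20.54
    n_reference: int = 400
    ridge: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_markers", "n_panel_haplotypes", "n_individuals",
                     "n_founders", "n_traits", "n_reference"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 < self.af_low <= self.af_high < 1.0:
            raise ConfigError(
                f"need 0 < af_low <= af_high < 1, got ({self.af_low}, {self.af_high})"
            )
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ConfigError(f"switch_rate must be in [0, 1], got {self.switch_rate}")
        if self.coverage < 0:
            raise ConfigError(f"coverage must be >= 0, got {self.coverage}")
        if self.base_quality <= 0:
            raise ConfigError(f"base_quality must be > 0, got {self.base_quality}")
        if self.effect_sd <= 0:
            raise ConfigError(f"effect_sd must be > 0, got {self.effect_sd}")
        if self.ridge <= 0:
            raise ConfigError(f"ridge must be > 0, got {self.ridge}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes: (haplotypes x markers) 0/1 alleles."""

    alleles: np.ndarray
    loci: pd.DataFrame
    phased: bool = True

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.loci):
            raise ConfigError("panel allele matrix does not match locus list")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ConfigError("panel alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def alt_freq(self) -> np.ndarray:
        """Empirical panel alternate-allele frequency per marker."""
        return self.alleles.mean(axis=0)


@dataclass
class TrueGenotypes:
    """Ground-truth dosages for simulated individuals plus haplotype pairs."""

    dosages: np.ndarray  # (n, m) int in {0,1,2}
    haplotypes: np.ndarray  # (n, 2, m) source alleles
    samples: list[str]
    loci: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ConfigError("true dosages must be 0/1/2")
        if not (self.haplotypes.sum(axis=1) == self.dosages).all():
            raise ConfigError("dosages inconsistent with source haplotypes")

    def as_matrix(self, role: str = "M") -> GenotypeMatrix:
        return GenotypeMatrix(
            samples=self.samples,
            loci=self.loci,
            dosages=self.dosages.astype(float),
            role=role,
        )


def _mosaic(templates: np.ndarray, n_out: int, switch_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    """Copy rows of ``templates`` as mosaics with per-interval switching.

    Template identity is a Markov chain along the marker axis: start from a
    uniform template, and at each adjacent-marker interval resample a
    uniform template with probability ``switch_rate``.
    """
    n_templates, m = templates.shape
    picks = rng.integers(0, n_templates, size=(n_out, m))
    switch = rng.random(size=(n_out, m)) < switch_rate
    switch[:, 0] = True  # first marker always takes its fresh pick
    # forward-fill template identity between switch points
    idx = np.where(switch, np.arange(m), 0)
    idx = np.maximum.accumulate(idx, axis=1)
    chosen = picks[np.arange(n_out)[:, None], idx]
    return templates[chosen, np.arange(m)[None, :]]


def _make_loci(m: int, alt_freq: np.ndarray | None = None) -> pd.DataFrame:
    loci = pd.DataFrame(
        {
            "locus_id": [f"snp{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,  # evenly spaced, order is what matters
            "ref": "A",
            "alt": "G",
            "alt_freq": np.nan if alt_freq is None else alt_freq,
        }
    )
    return validate_loci(loci)


def simulate_panel(cfg: SimConfig) -> HaplotypePanel:
    """Build the phased reference panel as founder mosaics.

    Founder haplotypes are marker-wise Bernoulli(p_i) draws with
    p_i ~ Uniform(af_low, af_high); panel haplotypes copy founders with
    template switching at ``switch_rate``. LocusInfo records carry the
    *panel empirical* alternate-allele frequency, which is the frequency
    the allele-frequency fill strategy consumes downstream.
    """
    rng = substream(cfg.seed, "panel")
    p = rng.uniform(cfg.af_low, cfg.af_high, size=cfg.n_markers)
    founders = (rng.random((cfg.n_founders, cfg.n_markers)) < p).astype(np.int8)
    alleles = _mosaic(founders, cfg.n_panel_haplotypes, cfg.switch_rate, rng)
    panel = HaplotypePanel(alleles=alleles, loci=_make_loci(cfg.n_markers))
    panel.loci["alt_freq"] = panel.alt_freq()
    return panel


def sample_individuals(
    panel: HaplotypePanel, n_individuals: int, seed: int, switch_rate: float = 0.05
) -> TrueGenotypes:
    """Draw diploid individuals as mosaic haplotype pairs from the panel."""
    if n_individuals < 1:
        raise ConfigError(f"n_individuals must be >= 1, got {n_individuals}")
    if panel.n_haplotypes < 1:
        raise ConfigError("empty haplotype panel")
    rng = substream(seed, "individuals")
    haps = _mosaic(panel.alleles, 2 * n_individuals, switch_rate, rng)
    haps = haps.reshape(n_individuals, 2, -1)
    return TrueGenotypes(
        dosages=haps.sum(axis=1),
        haplotypes=haps,
        samples=[f"ind{i + 1}" for i in range(n_individuals)],
        loci=panel.loci.copy(),
    )


def simulate_effects(
    cfg: SimConfig, seed: int | None = None, method: str = "backsolve"
) -> pd.DataFrame:
    """Highly polygenic marker effects, one column per trait.

    ``method="backsolve"`` (default) emulates how SNP-BLUP effect tables
    are produced in practice: true per-marker effects are drawn i.i.d.
    Normal, turned into breeding values of a reference cohort sampled
    from the simulated panel, and back-solved by ridge regression

        g_hat = Z_c' (Z_c Z_c' + lambda I)^(-1) u,   u = Z_c gamma,

    with Z_c the column-centered reference dosage matrix and
    lambda = ridge * tr(Z_c Z_c') / n_reference. Back-solved effects are
    aligned with the population's genotype covariance, which real
    back-solved solutions are by construction; each trait is rescaled to
    per-marker standard deviation ``effect_sd``.

    ``method="iid"`` returns the raw Normal(0, effect_sd^2) draws
    instead (no alignment with the population structure).

    Effects are expressed per copy of the alternate allele. Under either
    method the largest single-marker share of the summed magnitude is of
    order 1/m — the signature of a highly polygenic architecture.
    """
    master = cfg.seed if seed is None else seed
    rng = substream(master, "effects")
    gamma = rng.normal(0.0, cfg.effect_sd, size=(cfg.n_markers, cfg.n_traits))
    if method == "iid":
        effects = gamma
    elif method == "backsolve":
        panel = simulate_panel(cfg)
        ref_rng = substream(master, "reference")
        ref = _mosaic(panel.alleles, 2 * cfg.n_reference, cfg.switch_rate, ref_rng)
        z = ref.reshape(cfg.n_reference, 2, -1).sum(axis=1).astype(float)
        zc = z - z.mean(axis=0)
        u = zc @ gamma
        k = zc @ zc.T
        lam = cfg.ridge * np.trace(k) / cfg.n_reference
        effects = zc.T @ np.linalg.solve(k + lam * np.eye(cfg.n_reference), u)
        sd = effects.std(axis=0)
        scale = np.divide(cfg.effect_sd, sd, out=np.ones_like(sd), where=sd > 0)
        effects = effects * scale
    else:
        raise ConfigError(f"unknown effect method {method!r}")
    loci = _make_loci(cfg.n_markers)
    out = loci[["chrom", "pos", "ref", "alt"]].copy()
    for t in range(cfg.n_traits):
        out[f"trait{t + 1}"] = effects[:, t]
    return out


def simulate_pileup(
    truth: TrueGenotypes, cfg: SimConfig, seed: int | None = None,
    other_rate: float = 0.0,
) -> AlleleCountMatrix:
    """Simulate per-locus allele counts from true genotypes.

    Depth is Poisson(coverage) per individual x locus. Each read samples
    one of the two true alleles uniformly and is then miscalled with
    probability e = 10^(-Q/10); a symmetric ref<->alt flip by default.
    With ``other_rate`` > 0 that fraction of error reads lands in the
    ``other`` bucket instead (third-allele errors), exercising the
    genotyper's handling of reads matching neither target allele.

    Marginally each read is alt with probability (g/2)(1-e) + (1-g/2)e for
    true dosage g, so counts are drawn binomially given depth.
    """
    rng = substream(cfg.seed if seed is None else seed, "pileup")
    g = truth.dosages.astype(float)
    e = 10.0 ** (-cfg.base_quality / 10.0)
    depth = rng.poisson(cfg.coverage, size=g.shape)
    p_alt = (g / 2.0) * (1.0 - e) + (1.0 - g / 2.0) * e
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    other = np.zeros_like(ref)
    if other_rate > 0.0:
        # error reads were flipped to the opposite target allele; reroute a
        # fraction of them to a non-target base
        p_err_given_alt = np.clip(
            np.where(p_alt > 0, (1.0 - g / 2.0) * e / np.maximum(p_alt, 1e-300), 0.0),
            0.0, 1.0,
        )
        p_err_given_ref = np.clip(
            np.where(1.0 - p_alt > 0, (g / 2.0) * e / np.maximum(1.0 - p_alt, 1e-300), 0.0),
            0.0, 1.0,
        )
        mis_alt = rng.binomial(alt, p_err_given_alt * other_rate)
        mis_ref = rng.binomial(ref, p_err_given_ref * other_rate)
        alt -= mis_alt
        ref -= mis_ref
        other = mis_alt + mis_ref
    return AlleleCountMatrix(
        samples=truth.samples, loci=truth.loci.copy(), ref=ref, alt=alt, other=other
    )


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Serialize the panel as a phased VCF, two haplotypes per pseudo-sample.

    Haplotype 2k goes to GT position 0 of sample k and haplotype 2k+1 to
    position 1, so phase round-trips through ``core.read_panel_vcf``.
    """
    import io as _io

    from .core import _vcf_header

    if panel.n_haplotypes % 2:
        raise ConfigError("panel VCF output needs an even haplotype count")
    n = panel.n_haplotypes // 2
    h = panel.alleles.reshape(n, 2, -1)
    samples = [f"panel{i + 1}" for i in range(n)]
    contigs = list(dict.fromkeys(panel.loci["chrom"].astype(str)))
    buf = _io.StringIO()
    buf.write(_vcf_header(samples, contigs))
    for j in range(len(panel.loci)):
        row = panel.loci.iloc[j]
        fields = [str(row["chrom"]), str(int(row["pos"])), str(row["locus_id"]),
                  str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT"]
        fields += [f"{h[i, 0, j]}|{h[i, 1, j]}" for i in range(n)]
        buf.write("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
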