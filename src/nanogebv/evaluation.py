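"""Evaluation of sequence-derived predictions against the array reference.

Three views, per trait / coverage / fill method:

* genotype concordance classes — per cell the number of correctly called
  alleles is 2 - |g_seq - g_array|, giving both-correct / one-wrong /
  both-wrong proportions (hard calls only; missing cells are excluded
  and counted separately);
* Pearson correlation between the sequence-derived GEBV (a) and the
  array GEBV (b);
* prediction bias — the OLS slope of b on a (with intercept). Slope 1
  means the sequence predictions are on the right scale; slope > 1 means
  they are under-dispersed (shrunk toward the mean), so high-merit
  individuals are under-predicted.

A two-stage residual regression checks whether per-sample sequencing
covariates (read length, base quality, ...) explain prediction error:
stage 1 regresses b on a, stage 2 regresses the stage-1 residuals on the
covariate and reports the slope with its two-sided t-test p-value
(significance convention: p <= 0.01, no multiplicity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import simdata
from .errors import ConfigError, DegenerateInputError, InputError
from .gebv import predict, trait_columns
from .genotyper import genotype_all
from .imputation import apply_fill
from .pileup_io import thin_counts

__all__ = [
    "concordance",
    "bias_regression",
    "correlation",
    "covariate_effect",
    "ExperimentConfig",
    "run_experiment",
]

SIGNIFICANCE_LEVEL = 0.01


def concordance(seq, array) -> dict:
    """Genotype-call agreement classes between two hard-called matrices.

    Accepts dosage arrays or GenotypeMatrix objects of identical shape
    and locus order. Cells missing in either matrix are excluded from
    the proportions and reported as ``n_missing``. Proportions sum to 1
    over the compared cells.
    """
    a = seq.dosages if hasattr(seq, "dosages") else np.asarray(seq, dtype=float)
    b = array.dosages if hasattr(array, "dosages") else np.asarray(array, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"shape mismatch: {a.shape} vs {b.shape}")
    ok = ~np.isnan(a) & ~np.isnan(b)
    av, bv = a[ok], b[ok]
    if np.any(av != np.round(av)) or np.any(bv != np.round(bv)):
        raise InputError("concordance requires hard (integer) calls")
    n = av.size
    if n == 0:
        raise DegenerateInputError("no cells to compare")
    correct_alleles = 2 - np.abs(av - bv)
    return {
        "both_correct": float(np.mean(correct_alleles == 2)),
        "one_wrong": float(np.mean(correct_alleles == 1)),
        "both_wrong": float(np.mean(correct_alleles == 0)),
        "n_compared": int(n),
        "n_missing": int(a.size - n),
    }


def _check_pair(b_hat, a_hat) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(b_hat, dtype=float).ravel()
    a = np.asarray(a_hat, dtype=float).ravel()
    if a.shape != b.shape:
        raise InputError("prediction vectors differ in length")
    if a.size < 2:
        raise DegenerateInputError("need at least two individuals")
    return b, a


def bias_regression(b_hat, a_hat) -> tuple[float, float]:
    """OLS of the array GEBV on the sequence GEBV: (slope, intercept).

    The slope is the prediction-bias statistic; it equals
    cov(b, a) / var(a).
    """
    b, a = _check_pair(b_hat, a_hat)
    if np.var(a) == 0:
        raise DegenerateInputError("zero variance in sequence-derived GEBV")
    res = stats.linregress(a, b)
    return float(res.slope), float(res.intercept)


def correlation(b_hat, a_hat) -> float:
    """Pearson correlation between the two prediction vectors."""
    b, a = _check_pair(b_hat, a_hat)
    if np.var(a) == 0 or np.var(b) == 0:
        raise DegenerateInputError("zero variance in a prediction vector")
    return float(stats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class CovariateEffect:
    slope: float
    stderr: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= SIGNIFICANCE_LEVEL


def covariate_effect(b_hat, a_hat, x) -> CovariateEffect:
    """Effect of a per-sample covariate on prediction error.

    Stage 1: OLS b ~ a; stage 2: OLS of the stage-1 residuals on x.
    Returns the stage-2 slope, its standard error and the two-sided
    t-test p-value.
    """
    b, a = _check_pair(b_hat, a_hat)
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != a.shape:
        raise InputError("covariate length does not match predictions")
    if a.size < 4:
        raise DegenerateInputError("need at least 4 individuals")
    if np.var(x) == 0:
        raise DegenerateInputError("degenerate covariate (zero variance)")
    slope1, intercept1 = bias_regression(b, a)
    resid = b - (intercept1 + slope1 * a)
    res = stats.linregress(x, resid)
    return CovariateEffect(
        slope=float(res.slope), stderr=float(res.stderr), p_value=float(res.pvalue)
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Full-factorial sweep: coverages x fill methods x traits.

    ``coverages`` below the simulated full coverage are reached by
    binomial read thinning of the full-coverage pileup, mirroring a
    subsampling of the sequencing run; a coverage equal to
    ``sim.coverage`` is the untouched full-coverage data.
    """

    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    coverages: tuple = (6.3, 4.0, 2.0, 1.0, 0.5)
    methods: tuple = ("non-imputed", "imputed-AF", "imputed-LD")
    threshold_target: float = 0.95
    ld_window: int = 10

    def __post_init__(self):
        for c in self.coverages:
            if not 0 < c <= self.sim.coverage:
                raise ConfigError(
                    f"coverage {c} outside (0, full={self.sim.coverage}]"
                )
        from .imputation import FILL_METHODS

        for m_ in self.methods:
            if m_ not in FILL_METHODS:
                raise ConfigError(f"unknown fill method {m_!r}")


def _thin_seed(master: int, idx: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(99, idx)).generate_state(1)[0] % 2**31)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate one cohort and evaluate the full sweep.

    One row per (coverage, fill method, trait) with correlation, bias
    slope/intercept, pre-fill concordance of the called genotypes against
    the truth, and per-coverage missingness. Deterministic given
    ``config.sim.seed``.
    """
    cfg = config.sim
    panel = simdata.simulate_panel(cfg)
    truth = simdata.sample_individuals(
        panel, cfg.n_individuals, cfg.seed, cfg.switch_rate
    )
    effects = simdata.simulate_effects(cfg)
    traits = trait_columns(effects)
    array_matrix = truth.as_matrix(role="M")
    b_hat = predict(array_matrix, effects)
    full_counts = simdata.simulate_pileup(truth, cfg)

    rows = []
    for ci, cov in enumerate(config.coverages):
        counts = (
            full_counts
            if cov == cfg.coverage
            else thin_counts(full_counts, cfg.coverage, cov, _thin_seed(cfg.seed, ci))
        )
        called = genotype_all(counts, config.threshold_target)
        conc = concordance(called, array_matrix)
        missing_rate = called.missing_mask.mean()
        for method in config.methods:
            filled = apply_fill(
                called, method, panel_alleles=panel.alleles, window=config.ld_window
            )
            a_hat = predict(filled, effects)
            for t in traits:
                slope, intercept = bias_regression(b_hat[t], a_hat[t])
                rows.append(
                    {
                        "trait": t,
                        "coverage": cov,
                        "method": method,
                        "pearson_r": correlation(b_hat[t], a_hat[t]),
                        "bias_slope": slope,
                        "bias_intercept": intercept,
                        "both_correct": conc["both_correct"],
                        "one_wrong": conc["one_wrong"],
                        "both_wrong": conc["both_wrong"],
                        "missing_rate": float(missing_rate),
                        "n_individuals": cfg.n_individuals,
                        "n_loci": cfg.n_markers,
                        "seed": cfg.seed,
                    }
                )
    return pd.DataFrame(rows)
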