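"""Variable minimum-allele-count genotyping from low-coverage allele counts.

A true heterozygote sequenced to depth d contributes alt reads
X ~ Binomial(d, 1/2); at low depth one allele is easily missed entirely,
so a fixed count threshold either miscalls heterozygotes or wastes data.
The rule used here adapts the threshold to depth: for each depth d the
minimum allele count t(d) is the *largest* integer t >= 1 such that a true
heterozygote shows both alleles at least t times with probability at least
the target (default 95%),

    P(t <= X <= d - t) >= target,   X ~ Binomial(d, 1/2),

falling back to t = 1 at depths too small for any t to reach the target
(d <= 5 at the 95% default). Choosing the largest qualifying t maximises
protection against sequencing-error reads faking a heterozygote while
keeping the both-alleles guarantee.

Call rule per cell (depth = ref + alt counts; ``other`` reads excluded):

* depth 0            -> MISSING (handed to a fill strategy)
* depth 1            -> homozygous for the single observed allele
* depth >= 2, t=t(d) -> heterozygous if both counts >= t, else homozygous
                        for the majority allele (equal counts with both
                        >= t are heterozygous).

Loci are grouped by exact integer depth — the finest coverage grouping —
so t is simply a function of per-cell depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import (
    SOURCE_CALLED,
    SOURCE_MISSING,
    AlleleCountMatrix,
    GenotypeMatrix,
)
from .errors import ConfigError

__all__ = [
    "min_allele_count",
    "threshold_table",
    "call_genotype",
    "genotype_all",
    "het_miscall_probability",
]

MISSING = np.nan


def min_allele_count(depth: int, target: float = 0.95) -> int:
    """Minimum allele count t(d) for the both-alleles-observed rule.

    The largest t >= 1 with P(t <= X <= d-t) >= target for
    X ~ Binomial(d, 1/2); t = 1 when no threshold reaches the target.
    """
    if depth < 1:
        raise ConfigError(f"depth must be >= 1, got {depth}")
    if not 0.0 < target < 1.0:
        raise ConfigError(f"target must be in (0, 1), got {target}")
    # central probability is decreasing in t, so scan from the widest t down
    for t in range(depth // 2, 0, -1):
        p_central = binom.cdf(depth - t, depth, 0.5) - binom.cdf(t - 1, depth, 0.5)
        if p_central >= target:
            return t
    return 1


def threshold_table(max_depth: int, target: float = 0.95) -> pd.DataFrame:
    """t(d) for d = 1..max_depth as a two-column table."""
    if max_depth < 1:
        raise ConfigError("max_depth must be >= 1")
    return pd.DataFrame(
        {
            "depth": np.arange(1, max_depth + 1),
            "min_allele_count": [min_allele_count(d, target) for d in range(1, max_depth + 1)],
        }
    )


def call_genotype(ref_count: int, alt_count: int, target: float = 0.95) -> float:
    """Call one genotype from ref/alt read counts; NaN means missing.

    Depends only on the two counts (read order is irrelevant by
    construction). Returns dosage 0.0 / 1.0 / 2.0 or NaN at depth 0.
    """
    if ref_count < 0 or alt_count < 0:
        raise ConfigError("negative allele counts")
    depth = ref_count + alt_count
    if depth == 0:
        return MISSING
    if depth == 1:
        return 2.0 if alt_count == 1 else 0.0
    t = min_allele_count(depth, target)
    if ref_count >= t and alt_count >= t:
        return 1.0
    return 2.0 if alt_count > ref_count else 0.0


def genotype_all(
    counts: AlleleCountMatrix, target: float = 0.95
) -> GenotypeMatrix:
    """Vectorised genotype calling over a full counts matrix.

    Cells with zero depth (including loci absent from the pileup) are
    MISSING. Per-sample missingness is available from the returned
    matrix's :meth:`~nanogebv.core.GenotypeMatrix.missingness_per_sample`.
    """
    ref, alt = counts.ref, counts.alt
    depth = ref + alt
    d_max = int(depth.max()) if depth.size else 0
    # lookup t for every depth value present; t[0] unused
    t_of_d = np.ones(max(d_max, 1) + 1, dtype=np.int64)
    for d in range(2, d_max + 1):
        t_of_d[d] = min_allele_count(d, target)
    t = t_of_d[depth]
    dosages = np.where(alt > ref, 2.0, 0.0)  # majority allele (ties fall to het)
    het = (ref >= t) & (alt >= t) & (depth >= 2)
    dosages[het] = 1.0
    dosages[depth == 1] = np.where(alt[depth == 1] == 1, 2.0, 0.0)
    dosages[depth == 0] = MISSING
    source = np.where(depth == 0, SOURCE_MISSING, SOURCE_CALLED).astype(np.int8)
    return GenotypeMatrix(
        samples=list(counts.samples),
        loci=counts.loci.copy(),
        dosages=dosages,
        source=source,
        role="N",
    )


def het_miscall_probability(
    true_dosage: int, depth: int, error_rate: float, target: float = 0.95
) -> dict[str, float]:
    """Exact per-call outcome probabilities at fixed depth by enumeration.

    For a true genotype with per-read alt probability
    p = (g/2)(1-e) + (1-g/2)e, enumerates alt counts k = 0..d and sums the
    binomial weights of each called class. Useful as a closed-form check
    of the calling rule against simulation.
    """
    g = true_dosage
    p = (g / 2.0) * (1.0 - error_rate) + (1.0 - g / 2.0) * error_rate
    out = {"0": 0.0, "1": 0.0, "2": 0.0}
    if depth == 0:
        return {"missing": 1.0, **out}
    for k in range(depth + 1):
        w = binom.pmf(k, depth, p)
        call = call_genotype(depth - k, k, target)
        out[str(int(call))] += w
    return out
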