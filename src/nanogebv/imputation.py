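"""Filling strategies for missing genotypes.

Three strategies mirror how low-pass sequencing pipelines handle loci with
no reads:

* ``fill_homref`` — assign homozygous reference (dosage 0). Fast, but
  individuals with more missing loci receive systematically smaller
  predictions: the matrix-vector product simply loses their terms.
* ``fill_af`` — assign the Hardy-Weinberg expected dosage
  0*(1-p)^2 + 1*2p(1-p) + 2*p^2 = 2p for population alternate-allele
  frequency p: a continuous dosage that regresses every individual toward
  the population mean at the missing loci.
* ``impute_ld`` — a windowed haplotype-pair imputer that exploits linkage
  disequilibrium with a phased reference panel: for each missing cell,
  the panel haplotype pair that best matches the individual's called
  genotypes in a local marker window supplies the missing dosage (ties
  averaged). This is the built-in, deterministic stand-in for external
  phasing-based imputation software; ``beagle_adapter`` wires in Beagle
  5.1 when the executable is available.

No strategy ever alters a called cell.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile

import numpy as np

from .core import (
    SOURCE_FILLED_AF,
    SOURCE_FILLED_HOMREF,
    SOURCE_IMPUTED_BEAGLE,
    SOURCE_IMPUTED_LD,
    GenotypeMatrix,
    check_same_loci,
    read_genotypes_vcf,
    write_genotypes_vcf,
)
from .errors import BeagleUnavailableError, ConfigError, InputError

__all__ = ["fill_homref", "fill_af", "impute_ld", "beagle_adapter", "FILL_METHODS"]


def fill_homref(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Assign every missing cell dosage 0 (homozygous reference)."""
    out = matrix.copy()
    miss = out.missing_mask
    out.dosages[miss] = 0.0
    out.source[miss] = SOURCE_FILLED_HOMREF
    return out


def fill_af(matrix: GenotypeMatrix, alt_freq=None) -> GenotypeMatrix:
    """Assign missing cells the HWE expected dosage 2p.

    ``alt_freq`` defaults to the matrix's locus table ``alt_freq`` column.
    An individual missing everywhere receives the population-mean
    prediction sum_i 2 p_i g_i downstream — the mechanism behind the
    regression-toward-the-mean bias of this strategy.
    """
    p = (
        matrix.loci["alt_freq"].to_numpy(dtype=float)
        if alt_freq is None
        else np.asarray(alt_freq, dtype=float)
    )
    if p.shape != (len(matrix.loci),):
        raise InputError("alt_freq length does not match locus count")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("alt_freq must be in [0, 1] for every locus")
    out = matrix.copy()
    miss = out.missing_mask
    out.dosages[miss] = np.broadcast_to(2.0 * p, out.dosages.shape)[miss]
    out.source[miss] = SOURCE_FILLED_AF
    return out


def _pair_index(n_hap: int) -> tuple[np.ndarray, np.ndarray]:
    """Unordered haplotype pair indices (i <= j), including self-pairs."""
    i, j = np.triu_indices(n_hap)
    return i, j


def impute_ld(
    matrix: GenotypeMatrix,
    panel_alleles: np.ndarray,
    panel_loci=None,
    window: int = 10,
) -> GenotypeMatrix:
    """Impute missing cells from the best-matching panel haplotype pair.

    For each missing cell the surrounding window of up to ``window``
    called loci on each side is compared against the dosages of every
    (unordered) panel haplotype pair; the pair(s) matching the most
    window loci supply the imputed dosage, averaging over ties. Scores
    and dosages are symmetric in the pair, so unordered pairs give the
    same tie-average as ordered ones. Missing cells sharing the same
    flanking called loci share one window and are imputed together.

    Cells with no called locus in the window (e.g. an individual with no
    calls at all) fall back to the HWE dosage from the locus table's
    ``alt_freq`` and are labelled ``filled-af``.
    """
    panel_alleles = np.asarray(panel_alleles, dtype=np.int8)
    if panel_alleles.size == 0:
        raise ConfigError("empty haplotype panel")
    if panel_alleles.shape[1] != len(matrix.loci):
        raise ConfigError("panel marker count does not match matrix")
    if panel_loci is not None:
        check_same_loci(matrix.loci, panel_loci, "matrix vs panel")
    if window < 1:
        raise ConfigError("window must be >= 1")

    n, m = matrix.dosages.shape
    hi, hj = _pair_index(panel_alleles.shape[0])
    pair_dose = (panel_alleles[hi] + panel_alleles[hj]).astype(np.int8)  # (P, m)
    out = matrix.copy()
    af = matrix.loci["alt_freq"].to_numpy(dtype=float)

    for ind in range(n):
        row = matrix.dosages[ind]
        called = np.flatnonzero(~np.isnan(row))
        miss = np.flatnonzero(np.isnan(row))
        if miss.size == 0:
            continue
        if called.size == 0:
            if np.isnan(af[miss]).any():
                raise InputError(
                    "individual with no called loci needs alt_freq for fallback"
                )
            out.dosages[ind, miss] = 2.0 * af[miss]
            out.source[ind, miss] = SOURCE_FILLED_AF
            continue
        # group missing cells by their position between called loci: all
        # cells in one inter-call gap share the same window
        gap = np.searchsorted(called, miss)  # cells precede called[gap]
        groups, inverse = np.unique(gap, return_inverse=True)
        G = groups.size
        w = 2 * window
        win = np.full((G, w), -1, dtype=np.int64)
        for gi, g in enumerate(groups):
            left = called[max(0, g - window) : g]
            right = called[g : g + window]
            ctx = np.concatenate([left, right])
            win[gi, : ctx.size] = ctx
        valid = win >= 0
        win_safe = np.where(valid, win, 0)
        # score every pair against the called dosages in each window
        g_called = row[win_safe]  # (G, w)
        eq = (pair_dose[:, win_safe] == g_called[None, :, :]) & valid[None, :, :]
        scores = eq.sum(axis=2)  # (P, G)
        best = scores == scores.max(axis=0, keepdims=True)
        weights = best / best.sum(axis=0, keepdims=True)  # (P, G)
        # imputed dosage = tie-averaged pair dosage at each missing locus
        wsel = weights[:, inverse]  # (P, n_miss)
        imputed = np.einsum("pc,pc->c", wsel, pair_dose[:, miss].astype(float))
        out.dosages[ind, miss] = np.clip(imputed, 0.0, 2.0)
        out.source[ind, miss] = SOURCE_IMPUTED_LD
    return out


FILL_METHODS = {
    "non-imputed": "fill_homref",
    "imputed-AF": "fill_af",
    "imputed-LD": "impute_ld",
}


def apply_fill(matrix: GenotypeMatrix, method: str, panel_alleles=None,
               window: int = 10) -> GenotypeMatrix:
    """Dispatch a fill strategy by name (see :data:`FILL_METHODS`)."""
    if method in ("non-imputed", "homref"):
        return fill_homref(matrix)
    if method in ("imputed-AF", "af"):
        return fill_af(matrix)
    if method in ("imputed-LD", "ld"):
        if panel_alleles is None:
            raise ConfigError("imputed-LD requires a haplotype panel")
        return impute_ld(matrix, panel_alleles, window=window)
    raise ConfigError(f"unknown fill method {method!r}")


def beagle_adapter(
    matrix: GenotypeMatrix,
    panel_vcf: str,
    beagle_command: str | None = None,
    ne: int = 100_000,
    window_cm: float = 100.0,
    extra_args: tuple[str, ...] = (),
) -> GenotypeMatrix:
    """Impute missing genotypes through an external Beagle 5.1 run.

    Writes the called genotypes as a VCF with missing GT, invokes Beagle
    with the supplied reference panel, effective population size ``ne``
    (default 100,000) and window size ``window_cm`` (default 100; raise
    toward ~158 cM for very sparse 0.5x data so called markers still
    overlap the panel per chromosome window), then reads the imputed GT
    back as dosages.

    With no missing cells the input is returned unchanged without
    invoking the program. Raises :class:`BeagleUnavailableError` when no
    executable is found; the built-in :func:`impute_ld` covers the same
    pipeline arm without the external dependency.
    """
    if matrix.n_missing == 0:
        return matrix.copy()
    cmd = beagle_command or shutil.which("beagle") or os.environ.get("BEAGLE_JAR")
    if cmd is None:
        raise BeagleUnavailableError(
            "no Beagle executable found (looked for 'beagle' on PATH and "
            "$BEAGLE_JAR); use nanogebv.imputation.impute_ld instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        gt_vcf = os.path.join(tmp, "calls.vcf")
        out_prefix = os.path.join(tmp, "imputed")
        write_genotypes_vcf(matrix, gt_vcf)
        argv = (
            [cmd]
            if not str(cmd).endswith(".jar")
            else ["java", "-jar", str(cmd)]
        )
        argv += [
            f"gt={gt_vcf}",
            f"ref={panel_vcf}",
            f"out={out_prefix}",
            f"ne={ne}",
            f"window={window_cm}",
            *extra_args,
        ]
        subprocess.run(argv, check=True, capture_output=True)
        vcf_out = out_prefix + ".vcf.gz"
        if not os.path.exists(vcf_out):
            vcf_out = out_prefix + ".vcf"
        imputed = read_genotypes_vcf(vcf_out, role=matrix.role)
    check_same_loci(matrix.loci, imputed.loci, "input vs Beagle output")
    out = matrix.copy()
    miss = out.missing_mask
    out.dosages[miss] = imputed.dosages[miss]
    out.source[miss] = SOURCE_IMPUTED_BEAGLE
    return out
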