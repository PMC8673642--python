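"""SNP-BLUP genomic predictions: GEBV = genotype matrix x marker effects.

With marker effects g (one per locus per trait, expressed per copy of the
alternate allele) and an n x m dosage matrix, the predicted breeding
values are the plain matrix-vector product per trait — b = M g for the
array-derived reference matrix M and a = N g for the sequence-derived
matrix N. Dosages are the raw 0..2 alt-allele counts (no centering); any
resulting location shift is absorbed by the intercept of the evaluation
regressions.

Estimating the effects themselves (the mixed-model back-solve) is out of
scope: effects arrive as a table keyed by (chrom, pos, ref, alt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .errors import DegenerateInputError, InputError, PredictionError

__all__ = ["predict", "effect_share", "align_effects", "trait_columns",
           "read_effects_tsv", "write_effects_tsv"]

_KEY = ["chrom", "pos", "ref", "alt"]


def trait_columns(effects: pd.DataFrame) -> list[str]:
    cols = [c for c in effects.columns if c not in _KEY]
    if not cols:
        raise InputError("marker-effect table has no trait columns")
    return cols


def read_effects_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _KEY if c not in df.columns]
    if missing:
        raise InputError(f"effects table missing columns: {missing}")
    return df


def write_effects_tsv(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, sep="\t", index=False)


def _check_alignment(matrix: GenotypeMatrix, effects: pd.DataFrame) -> None:
    if len(effects) != len(matrix.loci):
        raise PredictionError(
            f"effects cover {len(effects)} loci, matrix has {len(matrix.loci)}"
        )
    for k in _KEY:
        a = matrix.loci[k].to_numpy()
        b = effects[k].to_numpy()
        bad = np.flatnonzero(a != b)
        if bad.size:
            j = bad[0]
            raise PredictionError(
                f"locus mismatch at column {j}: matrix {k}={a[j]!r} vs "
                f"effects {k}={b[j]!r} (effects are never silently reordered; "
                "run align_effects first)"
            )


def predict(matrix: GenotypeMatrix, effects: pd.DataFrame) -> pd.DataFrame:
    """GEBV per individual per trait: the dosage-weighted effect sum.

    The matrix must be fully filled (no missing cells) and its locus list
    must match the effect table exactly, in order; misalignment is an
    error naming the first offending locus.

    Returns a DataFrame indexed by sample with one column per trait.
    """
    _check_alignment(matrix, effects)
    if matrix.missing_mask.any():
        i, j = np.argwhere(matrix.missing_mask)[0]
        raise PredictionError(
            f"missing genotype at sample {matrix.samples[i]!r}, locus "
            f"{matrix.loci['locus_id'].iloc[j]!r}: run a fill method first"
        )
    traits = trait_columns(effects)
    g = effects[traits].to_numpy(dtype=float)
    if not np.isfinite(g).all():
        bad = np.argwhere(~np.isfinite(g))[0]
        raise PredictionError(
            f"non-finite effect at locus {effects.iloc[bad[0]][_KEY].tolist()}"
        )
    values = matrix.dosages @ g
    return pd.DataFrame(values, index=pd.Index(matrix.samples, name="sample_id"),
                        columns=traits)


def effect_share(effects: pd.DataFrame) -> pd.DataFrame:
    """Signed per-marker share of the total effect, E_i / sum_j |E_j|.

    The shares of one trait sum to 1 in absolute value; a highly
    polygenic architecture shows a largest |share| of order 1/m.
    """
    traits = trait_columns(effects)
    out = effects[_KEY].copy()
    for t in traits:
        e = effects[t].to_numpy(dtype=float)
        total = np.abs(e).sum()
        if total == 0:
            raise DegenerateInputError(f"all-zero effects for trait {t!r}")
        out[t] = e / total
    return out


def align_effects(
    effects: pd.DataFrame, loci: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reorder an effects table onto a locus list, fixing allele swaps.

    Records whose (ref, alt) are swapped relative to the locus list have
    alleles swapped back and effect signs flipped (dosage d of one allele
    is 2 - d of the other: the slope changes sign, the constant shift is
    absorbed by evaluation intercepts). Unmatched loci in either
    direction are reported, never silently dropped.

    Returns ``(aligned_effects, rejects)`` where rejects lists locus-list
    entries with no effect record and effect records matching no locus.
    """
    if effects.duplicated(subset=_KEY).any():
        raise InputError("duplicate (chrom, pos, ref, alt) keys in effects table")
    traits = trait_columns(effects)

    def key_frame(df, flip):
        k = df[_KEY].copy()
        if flip:
            k[["ref", "alt"]] = k[["alt", "ref"]].to_numpy()
        return pd.MultiIndex.from_frame(k.astype({"pos": int}))

    eff_direct = pd.DataFrame(
        effects[traits].to_numpy(), index=key_frame(effects, False), columns=traits
    )
    eff_flipped = pd.DataFrame(
        -effects[traits].to_numpy(), index=key_frame(effects, True), columns=traits
    )
    want = pd.MultiIndex.from_frame(loci[_KEY].astype({"pos": int}))
    direct_hit = want.isin(eff_direct.index)
    flip_hit = ~direct_hit & want.isin(eff_flipped.index)
    matched = direct_hit | flip_hit
    values = np.full((len(loci), len(traits)), np.nan)
    if direct_hit.any():
        values[direct_hit] = eff_direct.loc[want[direct_hit]].to_numpy()
    if flip_hit.any():
        values[flip_hit] = eff_flipped.loc[want[flip_hit]].to_numpy()
    aligned = loci[_KEY].copy()
    for i, t in enumerate(traits):
        aligned[t] = values[:, i]
    aligned = aligned[matched].reset_index(drop=True)

    used = key_frame(effects, False).isin(want) | key_frame(effects, True).isin(want)
    rejects = pd.concat(
        [
            loci.loc[~matched, _KEY].assign(reason="no effect record"),
            effects.loc[~used, _KEY].assign(reason="no matching locus"),
        ],
        ignore_index=True,
    )
    return aligned, rejects
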