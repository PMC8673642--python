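"""Pileup parsing, coverage thinning and sequencing-run summaries.

The entry format is the 6-column ``samtools mpileup`` text output
(chrom, pos, ref, depth, read bases, base qualities). Only the read-base
column is decoded here — mapping-quality filtering happens upstream of the
pileup, and base qualities do not enter the genotyping rule — so this
module reduces each target locus to ref/alt/other read counts.

No installed library parses mpileup *text* (pysam pileups require BAM
input), so the read-base decoder is implemented here against the format
specification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import validate_loci
from .errors import ConfigError, DegenerateInputError, ParseError

__all__ = [
    "read_mpileup",
    "decode_read_bases",
    "thin_counts",
    "summarize_run",
    "phred_error_rate",
    "example_run_table",
]


def phred_error_rate(q: float | np.ndarray) -> float | np.ndarray:
    """Per-base error probability for a Phred-scaled quality Q: 10^(-Q/10).

    Q20 corresponds to a 1% error rate; the scale is strictly decreasing
    in Q.
    """
    q = np.asarray(q, dtype=float)
    if (q <= 0).any():
        raise ConfigError("Phred quality must be > 0")
    out = 10.0 ** (-q / 10.0)
    return float(out) if out.ndim == 0 else out


def decode_read_bases(bases: str, line_number: int | None = None) -> list[str]:
    """Decode an mpileup read-base string into one symbol per read.

    Returns uppercase base letters for mismatches and ``.`` for
    reference-matching reads (``,`` is folded into ``.``). Markers that do
    not represent a base at this position are stripped: ``^q`` read-start
    (the following character is a mapping quality, not a base), ``$``
    read-end, ``+n<seq>``/``-n<seq>`` indels following a base, and ``*``
    deletion placeholders (which consume a read but no base call).
    """
    out: list[str] = []
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise ParseError("dangling '^' read-start marker", line_number)
            i += 2  # skip the mapping-quality character
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(f"indel marker '{c}' without length", line_number)
            i = j + int(bases[i + 1 : j])
        elif c == "*":
            i += 1  # deletion: read spans the site but contributes no base
        elif c in ".,":
            out.append(".")
            i += 1
        elif c.upper() in "ACGTN":
            out.append(c.upper())
            i += 1
        else:
            raise ParseError(f"unexpected pileup symbol {c!r}", line_number)
    return out


def read_mpileup(stream, loci: pd.DataFrame, sample_id: str = "sample") -> pd.DataFrame:
    """Reduce an mpileup text stream to allele counts at target loci.

    Parameters
    ----------
    stream
        Iterable of mpileup lines (an open text file works).
    loci
        Target locus table; loci absent from the stream yield zero counts.
    sample_id
        Sample label for the output rows (mpileup text carries none).

    Returns
    -------
    DataFrame with the allele-count schema plus a ``ref_mismatch`` flag
    set where the pileup reference base disagrees with the locus ref
    allele (counts are still produced for flagged records).
    """
    loci = validate_loci(loci)
    target = {
        (str(r.chrom), int(r.pos)): (str(r.ref).upper(), str(r.alt).upper(), idx)
        for idx, r in enumerate(loci.itertuples())
    }
    ref_c = np.zeros(len(loci), dtype=np.int64)
    alt_c = np.zeros(len(loci), dtype=np.int64)
    other_c = np.zeros(len(loci), dtype=np.int64)
    mismatch = np.zeros(len(loci), dtype=bool)
    for ln, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) == 1:  # tolerate space-separated toy inputs
            parts = line.split()
        if len(parts) < 6:
            # depth-0 lines may legally drop the last two columns
            if len(parts) == 4 and parts[3] == "0":
                parts = parts + ["", ""]
            else:
                raise ParseError(
                    f"expected 6 mpileup columns, got {len(parts)}", ln
                )
        chrom, pos_s, pile_ref, _depth, bases = parts[0], parts[1], parts[2], parts[3], parts[4]
        key = (chrom, int(pos_s))
        if key not in target:
            continue
        ref, alt, idx = target[key]
        if pile_ref.upper() != ref:
            mismatch[idx] = True
        for sym in decode_read_bases(bases, ln):
            if sym == ".":
                ref_c[idx] += 1
            elif sym == alt:
                alt_c[idx] += 1
            else:
                other_c[idx] += 1
    out = pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": loci["chrom"],
            "pos": loci["pos"],
            "ref_count": ref_c,
            "alt_count": alt_c,
            "other_count": other_c,
            "ref_mismatch": mismatch,
        }
    )
    return out


def thin_counts(counts, full_coverage: float, target_coverage: float, seed: int):
    """Binomially subsample reads down to a lower mean coverage.

    Each read (each unit of each count) is kept independently with
    probability ``target_coverage / full_coverage`` — distributionally
    equivalent, for counts, to subsampling the underlying read set.
    Accepts either a long counts DataFrame or an
    :class:`~nanogebv.core.AlleleCountMatrix`; returns the same type.
    """
    if not 0 < target_coverage <= full_coverage:
        raise ConfigError(
            f"need 0 < target ({target_coverage}) <= full ({full_coverage})"
        )
    if target_coverage == full_coverage:
        return counts.copy()
    p = target_coverage / full_coverage
    rng = np.random.default_rng(seed)
    if isinstance(counts, pd.DataFrame):
        out = counts.copy()
        for col in ("ref_count", "alt_count", "other_count"):
            out[col] = rng.binomial(out[col].to_numpy(), p)
        return out
    from .core import AlleleCountMatrix

    return AlleleCountMatrix(
        samples=list(counts.samples),
        loci=counts.loci.copy(),
        ref=rng.binomial(counts.ref, p),
        alt=rng.binomial(counts.alt, p),
        other=rng.binomial(counts.other, p),
    )


@dataclass(frozen=True)
class RunRecord:
    """Per-sample sequencing-run covariates."""

    sample_id: str
    mean_read_length: float
    yield_gb: float
    mean_base_quality: float
    mq0_reads: int
    unmapped_reads: int
    total_reads: int


def effective_read_pct(mq0_reads, unmapped_reads, total_reads):
    """Percentage of raw reads that map with nonzero mapping quality:
    (1 - (MQ0 + unmapped) / total) * 100."""
    total = np.asarray(total_reads, dtype=float)
    if (total <= 0).any():
        raise DegenerateInputError("effective-read percentage undefined for 0 reads")
    return (1.0 - (np.asarray(mq0_reads) + np.asarray(unmapped_reads)) / total) * 100.0


def summarize_run(records: list[RunRecord]) -> pd.DataFrame:
    """Per-sample run summary plus a cross-sample mean row.

    The returned table carries mean read length (bp), yield (Gb), mean
    base quality (the Phred sum over all bases divided by base count,
    taken here as given) and the effective-read percentage.
    """
    if not records:
        raise DegenerateInputError("no run records")
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "mean_read_length": [r.mean_read_length for r in records],
            "yield_gb": [r.yield_gb for r in records],
            "mean_base_quality": [r.mean_base_quality for r in records],
            "effective_read_pct": effective_read_pct(
                [r.mq0_reads for r in records],
                [r.unmapped_reads for r in records],
                [r.total_reads for r in records],
            ),
        }
    )
    mean_row = df.drop(columns="sample_id").mean()
    mean_row["sample_id"] = "mean"
    return pd.concat([df, mean_row.to_frame().T], ignore_index=True)[df.columns]


def example_run_table() -> pd.DataFrame:
    """Bundled example: per-animal MinION run summaries for a 19-heifer
    cattle cohort sequenced from tail hair (96-h runs, R9.4 chemistry)."""
    from importlib.resources import files

    path = files("nanogebv.data").joinpath("example_run_summary.tsv")
    return pd.read_csv(path, sep="\t")
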