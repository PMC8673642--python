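"""Shared containers: locus lists, allele-count tables and dosage matrices.

Conventions used throughout the package:

* Coordinates are 1-based inclusive (mpileup/VCF convention); ref and alt
  alleles are single bases on the reference forward strand.
* Dosage is the count of the alternate allele (0, 1 or 2 for hard calls;
  continuous values in [0, 2] for probabilistic fills).
* A missing genotype is ``NaN`` in the dosage matrix, paired with source
  code ``SOURCE_MISSING``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError

# Locus list schema: one row per target SNP.
LOCI_COLUMNS = ["locus_id", "chrom", "pos", "ref", "alt", "alt_freq"]

# Genotype provenance codes (GenotypeMatrix.source).
SOURCE_MISSING = -1
SOURCE_CALLED = 0
SOURCE_FILLED_HOMREF = 1
SOURCE_FILLED_AF = 2
SOURCE_IMPUTED_LD = 3
SOURCE_IMPUTED_BEAGLE = 4

SOURCE_NAMES = {
    SOURCE_MISSING: "missing",
    SOURCE_CALLED: "called",
    SOURCE_FILLED_HOMREF: "filled-homref",
    SOURCE_FILLED_AF: "filled-af",
    SOURCE_IMPUTED_LD: "imputed-ld",
    SOURCE_IMPUTED_BEAGLE: "imputed-beagle",
}

COUNT_COLUMNS = ["sample_id", "chrom", "pos", "ref_count", "alt_count", "other_count"]


def validate_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Validate a locus table and return it with canonical column order.

    Requires unique (chrom, pos), single-base ref != alt and alt_freq in
    [0, 1] where present (alt_freq may be NaN when no frequency is known).
    """
    missing = [c for c in LOCI_COLUMNS if c not in loci.columns and c != "alt_freq"]
    if missing:
        raise InputError(f"locus table missing columns: {missing}")
    loci = loci.copy()
    if "alt_freq" not in loci.columns:
        loci["alt_freq"] = np.nan
    if loci.duplicated(subset=["chrom", "pos"]).any():
        dup = loci[loci.duplicated(subset=["chrom", "pos"], keep=False)]
        raise InputError(
            f"duplicate (chrom, pos) in locus table: {dup[['chrom', 'pos']].values[:5]}"
        )
    if (loci["ref"] == loci["alt"]).any():
        raise InputError("locus table contains ref == alt records")
    af = loci["alt_freq"].to_numpy(dtype=float)
    ok = np.isnan(af) | ((af >= 0.0) & (af <= 1.0))
    if not ok.all():
        raise InputError("alt_freq outside [0, 1]")
    return loci[LOCI_COLUMNS].reset_index(drop=True)


def read_loci_tsv(path) -> pd.DataFrame:
    return validate_loci(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_loci_tsv(loci: pd.DataFrame, path) -> None:
    validate_loci(loci).to_csv(path, sep="\t", index=False)


@dataclass
class AlleleCountMatrix:
    """Per-sample, per-locus observed read counts in dense matrix form.

    ``ref``, ``alt`` and ``other`` are (n_samples, n_loci) integer arrays.
    Depth for genotyping purposes is ``ref + alt``; reads matching neither
    target allele are recorded in ``other`` but excluded from depth.
    """

    samples: list[str]
    loci: pd.DataFrame
    ref: np.ndarray
    alt: np.ndarray
    other: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        if self.other is None:
            self.other = np.zeros_like(self.ref)
        self.other = np.asarray(self.other, dtype=np.int64)
        n, m = len(self.samples), len(self.loci)
        for name, arr in (("ref", self.ref), ("alt", self.alt), ("other", self.other)):
            if arr.shape != (n, m):
                raise InputError(f"{name} counts have shape {arr.shape}, expected {(n, m)}")
            if (arr < 0).any():
                raise InputError(f"negative {name} counts")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def to_frame(self) -> pd.DataFrame:
        """Long-format counts table (one row per sample x locus)."""
        n, m = self.ref.shape
        return pd.DataFrame(
            {
                "sample_id": np.repeat(self.samples, m),
                "chrom": np.tile(self.loci["chrom"].to_numpy(), n),
                "pos": np.tile(self.loci["pos"].to_numpy(), n),
                "ref_count": self.ref.ravel(),
                "alt_count": self.alt.ravel(),
                "other_count": self.other.ravel(),
            }
        )

    @classmethod
    def from_frame(
        cls, counts: pd.DataFrame, loci: pd.DataFrame, samples: list[str] | None = None
    ) -> "AlleleCountMatrix":
        """Pivot a long counts table onto a locus list; absent cells get zero.

        Duplicate (sample, chrom, pos) records are an error: a pileup yields
        one record per site.
        """
        loci = validate_loci(loci)
        if samples is None:
            samples = sorted(counts["sample_id"].unique().tolist())
        if counts.duplicated(subset=["sample_id", "chrom", "pos"]).any():
            raise InputError("duplicate (sample, locus) records in counts table")
        key = counts["chrom"].astype(str) + ":" + counts["pos"].astype(str)
        locus_key = loci["chrom"].astype(str) + ":" + loci["pos"].astype(str)
        col = pd.Series(np.arange(len(loci)), index=locus_key)
        row = pd.Series(np.arange(len(samples)), index=samples)
        keep = key.isin(col.index) & counts["sample_id"].isin(row.index)
        counts = counts[keep]
        i = row[counts["sample_id"]].to_numpy()
        j = col[key[keep]].to_numpy()
        shape = (len(samples), len(loci))
        ref = np.zeros(shape, dtype=np.int64)
        alt = np.zeros(shape, dtype=np.int64)
        other = np.zeros(shape, dtype=np.int64)
        ref[i, j] = counts["ref_count"].to_numpy()
        alt[i, j] = counts["alt_count"].to_numpy()
        other[i, j] = counts["other_count"].to_numpy()
        return cls(samples=list(samples), loci=loci, ref=ref, alt=alt, other=other)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"counts table missing columns: {missing}")
    return df[COUNT_COLUMNS]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with per-cell provenance.

    ``dosages`` is float (n, m); missing cells are NaN. ``source`` is int8
    (n, m) with the SOURCE_* codes. ``role`` distinguishes the array-derived
    reference matrix (M) from the sequence-derived matrix (N).
    """

    samples: list[str]
    loci: pd.DataFrame
    dosages: np.ndarray
    source: np.ndarray = field(default=None)  # type: ignore[assignment]
    role: str = "N"

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.samples), len(self.loci)
        if self.dosages.shape != (n, m):
            raise InputError(
                f"dosage matrix has shape {self.dosages.shape}, expected {(n, m)}"
            )
        if self.source is None:
            src = np.full((n, m), SOURCE_CALLED, dtype=np.int8)
            src[np.isnan(self.dosages)] = SOURCE_MISSING
            self.source = src
        self.source = np.asarray(self.source, dtype=np.int8)
        if self.source.shape != (n, m):
            raise InputError("source matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosages) & ((self.dosages < 0) | (self.dosages > 2))
        if bad.any():
            raise InputError("dosages outside [0, 2]")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def missingness_per_sample(self) -> pd.Series:
        return pd.Series(
            self.missing_mask.mean(axis=1), index=self.samples, name="missing_rate"
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(self, dosages=self.dosages.copy(), source=self.source.copy())

    def is_hard_called(self) -> bool:
        d = self.dosages[~self.missing_mask]
        return bool(np.all(d == np.round(d)))


def write_dosage_tsv(matrix: GenotypeMatrix, path) -> None:
    """Write a loci x samples dosage table (NaN rendered as empty field)."""
    df = pd.DataFrame(
        matrix.dosages.T, index=matrix.loci["locus_id"], columns=matrix.samples
    )
    df.insert(0, "chrom", matrix.loci["chrom"].to_numpy())
    df.insert(1, "pos", matrix.loci["pos"].to_numpy())
    df.insert(2, "ref", matrix.loci["ref"].to_numpy())
    df.insert(3, "alt", matrix.loci["alt"].to_numpy())
    df.to_csv(path, sep="\t", index=True, index_label="locus_id")


def read_dosage_tsv(path, role: str = "N") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["locus_id", "chrom", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta]
    loci = df[meta].copy()
    loci["alt_freq"] = np.nan
    return GenotypeMatrix(
        samples=samples,
        loci=validate_loci(loci),
        dosages=df[samples].to_numpy(dtype=float).T,
        role=role,
    )


def _vcf_header(samples: list[str], contigs: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=nanogebv"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def write_genotypes_vcf(matrix: GenotypeMatrix, path, phased: bool = False) -> None:
    """Write hard genotype calls as VCF 4.2 GT records; missing as ``./.``.

    Continuous dosages cannot be represented in GT and raise an error.
    """
    d = matrix.dosages
    called = ~np.isnan(d)
    if not matrix.is_hard_called():
        raise InputError("VCF GT output requires hard (integer) genotype calls")
    sep = "|" if phased else "/"
    gt_map = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}
    contigs = list(dict.fromkeys(matrix.loci["chrom"].astype(str)))
    buf = io.StringIO()
    buf.write(_vcf_header(matrix.samples, contigs))
    loci = matrix.loci
    for j in range(len(loci)):
        row = loci.iloc[j]
        fields = [
            str(row["chrom"]),
            str(int(row["pos"])),
            str(row["locus_id"]),
            str(row["ref"]),
            str(row["alt"]),
            ".",
            "PASS",
            ".",
            "GT",
        ]
        col = d[:, j]
        fields += [
            gt_map[int(col[i])] if called[i, j] else f".{sep}."
            for i in range(len(matrix.samples))
        ]
        buf.write("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _iter_vcf_snps(path):
    """Yield (variant, locus record) for biallelic SNPs via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    for v in vcf:
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            continue  # only biallelic SNPs are modelled
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        yield v, (vid, v.CHROM, v.POS, v.REF, v.ALT[0]), vcf.samples


def read_genotypes_vcf(path, role: str = "N") -> GenotypeMatrix:
    """Read biallelic SNP GT records from a VCF into a dosage matrix."""
    records, dosage_rows, samples = [], [], []
    for v, rec, samples in _iter_vcf_snps(path):
        gts = v.gt_types.astype(float)  # gts012: 0/1/2 dosage, 3 = missing
        gts[gts == 3] = np.nan
        records.append(rec)
        dosage_rows.append(gts)
    loci = pd.DataFrame(records, columns=["locus_id", "chrom", "pos", "ref", "alt"])
    loci["alt_freq"] = np.nan
    return GenotypeMatrix(
        samples=list(samples),
        loci=validate_loci(loci),
        dosages=np.asarray(dosage_rows, dtype=float).T,
        role=role,
    )


def read_panel_vcf(path):
    """Read a phased panel VCF into (haplotypes x markers alleles, loci).

    Each diploid sample contributes two haplotype rows. Alleles must be
    fully called; alt_freq is the empirical panel frequency.
    """
    records, hap_cols, samples = [], [], []
    for v, rec, samples in _iter_vcf_snps(path):
        g = np.asarray(v.genotypes)[:, :2]  # (samples, 2 alleles)
        if (g < 0).any():
            raise InputError(f"panel VCF has missing alleles at {rec[1]}:{rec[2]}")
        records.append(rec)
        hap_cols.append(g.reshape(-1))
    alleles = np.asarray(hap_cols, dtype=np.int8).T  # (2*samples, markers)
    loci = pd.DataFrame(records, columns=["locus_id", "chrom", "pos", "ref", "alt"])
    loci["alt_freq"] = alleles.mean(axis=0)
    return alleles, validate_loci(loci)


def check_same_loci(a: pd.DataFrame, b: pd.DataFrame, what: str = "inputs") -> None:
    """Locus identity check by (chrom, pos, ref, alt); order must match."""
    keys = ["chrom", "pos", "ref", "alt"]
    if len(a) != len(b) or not all(
        (a[k].to_numpy() == b[k].to_numpy()).all() for k in keys
    ):
        raise InputError(f"locus lists of {what} differ (order-sensitive comparison)")
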