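"""mpileup decoding, coverage thinning, run summaries and Phred conversion."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanogebv import pileup_io
from nanogebv.core import (
    AlleleCountMatrix,
    read_counts_tsv,
    write_counts_tsv,
)
from nanogebv.errors import ConfigError, DegenerateInputError, ParseError
from nanogebv.pileup_io import (
    RunRecord,
    decode_read_bases,
    effective_read_pct,
    phred_error_rate,
    read_mpileup,
    summarize_run,
    thin_counts,
)


def _one_locus(toy_loci):
    return toy_loci.iloc[[0]].reset_index(drop=True)  # chr1:100 A->G


@pytest.mark.parametrize(
    "line, want",
    [
        # all reads match the reference
        ("chr1\t100\tA\t4\t.,.,\tIIII", (4, 0, 0)),
        # two reads carry the alt allele G
        ("chr1\t100\tA\t4\t.GG,\tIIII", (2, 2, 0)),
        # ^I is a read-start marker (next char is mapping quality); T is
        # neither ref nor alt -> other
        ("chr1\t100\tA\t3\t.T^I.\tIII", (2, 0, 1)),
        # indels and read ends are stripped; deletion placeholder is no base
        ("chr1\t100\tA\t6\t.+2AG.,-1c$,g*\t IIIIII", (4, 1, 0)),
        # lower-case alt counts the same as upper-case
        ("chr1\t100\tA\t2\tgG\tII", (0, 2, 0)),
    ],
)
def test_mpileup_read_base_decoding(toy_loci, line, want):
    counts = read_mpileup(io.StringIO(line + "\n"), _one_locus(toy_loci))
    got = counts.iloc[0]
    assert (got.ref_count, got.alt_count, got.other_count) == want


def test_absent_locus_yields_zero_counts(toy_loci):
    counts = read_mpileup(io.StringIO("chr1\t100\tA\t1\t.\tI\n"), toy_loci)
    assert counts.iloc[0].ref_count == 1
    assert (counts.iloc[1:][["ref_count", "alt_count", "other_count"]] == 0).all().all()


def test_malformed_line_reports_line_number(toy_loci):
    stream = io.StringIO("chr1\t100\tA\t4\t....\tIIII\nchr1\t200\tC\t3\n")
    with pytest.raises(ParseError, match="line 2"):
        read_mpileup(stream, toy_loci)


def test_reference_disagreement_is_flagged_not_dropped(toy_loci):
    counts = read_mpileup(io.StringIO("chr1\t100\tC\t2\t..\tII\n"), _one_locus(toy_loci))
    assert counts.iloc[0].ref_mismatch
    assert counts.iloc[0].ref_count == 2


def test_dangling_caret_is_a_parse_error():
    with pytest.raises(ParseError):
        decode_read_bases(".^", line_number=1)


def test_counts_tsv_roundtrip(tmp_path, toy_loci):
    counts = pd.DataFrame(
        {
            "sample_id": ["s1"] * 5,
            "chrom": toy_loci["chrom"],
            "pos": toy_loci["pos"],
            "ref_count": [3, 0, 1, 7, 2],
            "alt_count": [0, 2, 1, 0, 5],
            "other_count": [0, 0, 0, 1, 0],
        }
    )
    path = tmp_path / "c.tsv"
    write_counts_tsv(counts, path)
    back = read_counts_tsv(path)
    pd.testing.assert_frame_equal(back, counts)
    write_counts_tsv(back, tmp_path / "c2.tsv")
    assert (tmp_path / "c.tsv").read_bytes() == (tmp_path / "c2.tsv").read_bytes()


class TestThinning:
    def test_identity_when_target_equals_full(self, toy_loci):
        counts = pd.DataFrame(
            {
                "sample_id": "s1",
                "chrom": toy_loci["chrom"],
                "pos": toy_loci["pos"],
                "ref_count": [5, 1, 0, 3, 2],
                "alt_count": [0, 1, 0, 0, 4],
                "other_count": 0,
            }
        )
        out = thin_counts(counts, 4.0, 4.0, seed=1)
        pd.testing.assert_frame_equal(out, counts)

    def test_zero_counts_stay_zero(self, toy_loci):
        zero = pd.DataFrame(
            {
                "sample_id": "s1",
                "chrom": toy_loci["chrom"],
                "pos": toy_loci["pos"],
                "ref_count": 0,
                "alt_count": 0,
                "other_count": 0,
            }
        )
        out = thin_counts(zero, 4.0, 0.5, seed=1)
        assert (out[["ref_count", "alt_count", "other_count"]] == 0).all().all()

    def test_target_above_full_rejected(self):
        with pytest.raises(ConfigError):
            thin_counts(pd.DataFrame(), 2.0, 4.0, seed=1)

    def test_half_thinning_mean(self, rng):
        n = 20_000
        d = rng.poisson(6.0, size=n)
        counts = pd.DataFrame(
            {"sample_id": "s", "chrom": "1", "pos": np.arange(n) + 1,
             "ref_count": d, "alt_count": 0, "other_count": 0}
        )
        out = thin_counts(counts, 4.0, 2.0, seed=9)
        total, kept = d.sum(), out["ref_count"].sum()
        se = np.sqrt(total * 0.25)
        assert abs(kept - total / 2) <= 3 * se

    def test_two_stage_thinning_matches_one_stage(self, rng):
        """full->a->b thinning has the same mean as direct full->b."""
        n = 20_000
        d = rng.poisson(6.3, size=n)
        counts = pd.DataFrame(
            {"sample_id": "s", "chrom": "1", "pos": np.arange(n) + 1,
             "ref_count": d, "alt_count": 0, "other_count": 0}
        )
        two = thin_counts(thin_counts(counts, 6.3, 2.0, 1), 2.0, 0.5, 2)
        one = thin_counts(counts, 6.3, 0.5, 3)
        expected = d.sum() * 0.5 / 6.3
        se = np.sqrt(d.sum() * (0.5 / 6.3))
        assert abs(two["ref_count"].sum() - expected) <= 3 * se
        assert abs(one["ref_count"].sum() - expected) <= 3 * se

    def test_matrix_and_frame_paths_agree_in_distribution(self, toy_loci):
        mat = AlleleCountMatrix(
            samples=["s1"], loci=toy_loci,
            ref=np.array([[10, 10, 10, 10, 10]]),
            alt=np.array([[10, 10, 10, 10, 10]]),
        )
        out = thin_counts(mat, 4.0, 2.0, seed=5)
        assert out.ref.sum() + out.alt.sum() < 100
        assert (out.ref >= 0).all() and (out.alt >= 0).all()


class TestRunSummary:
    def test_effective_read_percentage_formula(self):
        assert effective_read_pct(0, 0, 100) == 100.0
        assert effective_read_pct(5, 5, 100) == 90.0
        with pytest.raises(DegenerateInputError):
            effective_read_pct(0, 0, 0)

    def test_summary_appends_mean_row(self):
        recs = [
            RunRecord("a", 1000, 20.0, 20.0, 5, 5, 100),
            RunRecord("b", 2000, 30.0, 22.0, 0, 0, 100),
        ]
        df = summarize_run(recs)
        mean = df[df.sample_id == "mean"].iloc[0]
        assert mean.mean_read_length == 1500
        assert mean.effective_read_pct == 95.0

    def test_bundled_cohort_means(self):
        """Column means of the bundled 19-animal MinION run table."""
        df = pileup_io.example_run_table()
        assert len(df) == 19
        assert round(df.mean_read_length.mean()) == 1795
        assert round(df.yield_gb.mean(), 2) == 22.57
        assert round(df.mean_base_quality.mean(), 2) == 20.54
        assert round(df.effective_read_pct.mean(), 1) == 86.4


@given(q=st.floats(min_value=0.1, max_value=60), dq=st.floats(min_value=0.01, max_value=10))
@settings(derandomize=True, max_examples=50)
def test_phred_error_rate_strictly_decreasing(q, dq):
    assert phred_error_rate(q + dq) < phred_error_rate(q)


def test_phred_closed_form_values():
    assert phred_error_rate(10) == pytest.approx(0.1)
    assert phred_error_rate(20) == pytest.approx(0.01)
    with pytest.raises(ConfigError):
        phred_error_rate(0)
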