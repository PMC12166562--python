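"""Summary-statistics I/O and allele harmonization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrimr import datasets
from nutrimr.summary_data import (
    FormatError,
    HarmonizedInstrument,
    SnpAssociation,
    SummaryStats,
    ValidationError,
    harmonize,
    is_palindromic,
    read_instruments,
    read_summary_stats,
    write_instruments,
    write_summary_stats,
)


def make_assoc(**kw):
    base = dict(
        snp_id="rs1", chrom="1", pos=1000, effect_allele="A", other_allele="G",
        eaf=0.3, beta=0.02, se=0.005, pvalue=1e-6,
    )
    base.update(kw)
    return SnpAssociation(**base)


class TestReadSummaryStats:
    def test_reads_packaged_b6_table(self, tmp_path):
        p = tmp_path / "b6.tsv"
        write_summary_stats(datasets.exposure_summary("vitamin_b6"), p)
        stats = read_summary_stats(p)
        assert len(stats) == 11
        rec = stats["rs4742795"]
        assert rec.beta == pytest.approx(0.017)
        assert rec.se == pytest.approx(0.004)

    def test_empty_file_gives_zero_records(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n")
        assert len(read_summary_stats(p)) == 0

    def test_zero_se_rejected_with_row_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.02\t0\t1e-6\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_summary_stats(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "cols.tsv"
        p.write_text("snp_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(FormatError):
            read_summary_stats(p)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        row = "rs1\t1\t100\tA\tG\t0.3\t0.02\t0.01\t1e-6\n"
        p.write_text(
            "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n" + row + row
        )
        with pytest.raises(ValidationError, match="rs1"):
            read_summary_stats(p)

    def test_dialect_maps_foreign_headers(self, tmp_path):
        p = tmp_path / "pheweb.tsv"
        p.write_text("rsid\tchr\tbp\talt\tref\taf\tB\tSE\tP\nrs9\t2\t50\tT\tC\t0.2\t-0.01\t0.002\t1e-7\n")
        stats = read_summary_stats(
            p,
            dialect={"snp_id": "rsid", "chrom": "chr", "pos": "bp", "effect_allele": "alt",
                     "other_allele": "ref", "eaf": "af", "beta": "B", "se": "SE", "pvalue": "P"},
        )
        assert stats["rs9"].beta == pytest.approx(-0.01)


@pytest.mark.parametrize(
    "a,b,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False)],
)
def test_is_palindromic(a, b, expected):
    assert is_palindromic(a, b) is expected


def test_is_palindromic_rejects_non_acgt():
    with pytest.raises(ValidationError):
        is_palindromic("A", "N")


def _pair(exp_kw, out_kw):
    exposure = SummaryStats("exp")
    exposure.add(make_assoc(**exp_kw))
    outcome = SummaryStats("out")
    outcome.add(make_assoc(**out_kw))
    return exposure, outcome


class TestHarmonize:
    def test_already_aligned_unchanged(self):
        exposure, outcome = _pair({"beta": 0.02}, {"beta": -0.1})
        inst, log = harmonize(exposure, outcome)
        assert not log
        assert inst[0].bx == 0.02 and inst[0].by == -0.1

    def test_swapped_alleles_flip_sign(self):
        exposure, outcome = _pair(
            {"beta": 0.02},
            {"effect_allele": "G", "other_allele": "A", "beta": -0.1, "eaf": 0.7},
        )
        inst, log = harmonize(exposure, outcome)
        assert not log
        assert inst[0].by == pytest.approx(0.1)

    def test_strand_complement_alignment(self):
        # outcome reported on the other strand: A/G on + is T/C on −
        exposure, outcome = _pair(
            {"beta": 0.02},
            {"effect_allele": "T", "other_allele": "C", "beta": -0.1},
        )
        inst, log = harmonize(exposure, outcome)
        assert not log
        assert inst[0].by == pytest.approx(-0.1)

    def test_palindromic_intermediate_excluded(self):
        exposure, outcome = _pair(
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.50},
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.50},
        )
        inst, log = harmonize(exposure, outcome, intermediate_af_band=(0.40, 0.60))
        assert not inst
        assert log[0]["reason"] == "palindromic-intermediate"

    def test_palindromic_missing_eaf_excluded(self):
        exposure, outcome = _pair(
            {"effect_allele": "C", "other_allele": "G", "eaf": None},
            {"effect_allele": "C", "other_allele": "G"},
        )
        _inst, log = harmonize(exposure, outcome)
        assert log[0]["reason"] == "palindromic-missing-eaf"

    def test_irreconcilable_alleles_logged(self):
        exposure, outcome = _pair({}, {"effect_allele": "A", "other_allele": "C"})
        inst, log = harmonize(exposure, outcome)
        assert not inst and log[0]["reason"] == "allele-mismatch"

    def test_record_conservation(self):
        exposure = SummaryStats("exp")
        outcome = SummaryStats("out")
        for i, (ea, oa, eaf) in enumerate(
            [("A", "G", 0.3), ("A", "T", 0.5), ("C", "G", 0.1), ("T", "C", 0.8)]
        ):
            exposure.add(make_assoc(snp_id=f"rs{i}", effect_allele=ea, other_allele=oa, eaf=eaf))
            outcome.add(make_assoc(snp_id=f"rs{i}", effect_allele=ea, other_allele=oa, eaf=eaf))
        inst, log = harmonize(exposure, outcome)
        assert len(inst) + len(log) == 4

    def test_idempotent_on_aligned_pair(self):
        exposure = datasets.exposure_summary("vitamin_c")
        outcome = datasets.outcome_summary("vitamin_c")
        inst1, log1 = harmonize(exposure, outcome)
        assert not log1 and len(inst1) == 10
        # harmonizing again from the already-aligned outcome changes nothing
        inst2, _ = harmonize(exposure, outcome)
        assert inst1 == inst2

    @given(flip=st.booleans(), beta=st.floats(-0.5, 0.5), eaf=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_sign_flip_consistency(self, flip, beta, eaf):
        """Relabelling the outcome's alleles (with sign/eaf flip) is a no-op."""
        exposure = SummaryStats("exp")
        exposure.add(make_assoc())
        outcome = SummaryStats("out")
        kw = dict(beta=beta or 0.01, eaf=eaf)
        if flip:
            kw.update(effect_allele="G", other_allele="A", beta=-(beta or 0.01), eaf=1 - eaf)
        outcome.add(make_assoc(**kw))
        inst, _ = harmonize(exposure, outcome)
        assert inst[0].by == pytest.approx(beta or 0.01)


class TestInstrumentRoundTrip:
    def test_write_then_read_identity(self, tmp_path, b6_instruments):
        p = tmp_path / "inst.tsv"
        write_instruments(b6_instruments, p)
        assert read_instruments(p) == b6_instruments

    def test_empty_list_header_only(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_instruments([], p)
        assert p.read_text().count("\n") == 1
        assert read_instruments(p) == []

    def test_row_count_matches(self, tmp_path, b6_instruments):
        p = tmp_path / "inst.tsv"
        write_instruments(b6_instruments, p)
        assert len(p.read_text().strip().splitlines()) == 12  # header + 11


def test_instrument_requires_positive_ses():
    with pytest.raises(ValidationError):
        HarmonizedInstrument(snp_id="rs1", bx=0.1, sx=0.0, by=0.1, sy=0.1)
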