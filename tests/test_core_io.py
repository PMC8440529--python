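"""Domain types, readers/writers, round-trips and coordinate conventions."""

import dataclasses

import pytest

from mrith import core_io
from mrith.core_io import (
    MutationCall,
    PatientReport,
    SchemaError,
    SegmentCN,
    ValidationError,
    from_half_open,
    read_mutation_table,
    read_segments,
    write_mutation_table,
    write_patient_report,
    write_segments,
)

from conftest import make_call, make_segment


class TestMutationCall:
    def test_vaf_from_counts(self):
        c = make_call(alt_reads=25, ref_reads=75)
        assert c.vaf == 0.25
        assert c.depth == 100

    def test_zero_depth_vaf(self):
        assert make_call(alt_reads=0, ref_reads=0).vaf == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ref": "A", "alt": "A"},
            {"alt_reads": -1},
            {"chrom": "27"},
            {"pos": 0},
            {"population_af": 1.5},
            {"effect": "missense"},
            {"context": "ACGT"},
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_call(**kwargs)

    def test_chr_prefix_normalized(self):
        assert make_call(chrom="chr1").chrom == "1"


class TestSegmentCN:
    def test_loh_flag(self):
        assert make_segment(total_cn=2.0, major_cn=2, minor_cn=0).is_loh
        assert not make_segment().is_loh

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"major_cn": 1, "minor_cn": 2, "total_cn": 3.0},
            {"start": 10, "end": 5},
            {"total_cn": 5.0},  # disagrees with major+minor=2
            {"end": 300_000_000},  # past chr1
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_segment(**kwargs)


class TestMutationTableIO:
    def test_three_row_tsv_parses_with_vaf_recomputed(self, tmp_path):
        calls = [
            make_call(pos=100 + i, alt_reads=10 * (i + 1), ref_reads=90)
            for i in range(3)
        ]
        path = tmp_path / "m.tsv"
        write_mutation_table(calls, path)
        back = read_mutation_table(path)
        assert len(back) == 3
        assert [c.vaf for c in back] == [0.1, 20 / 110, 30 / 120]

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_mutation_table([], path)
        assert read_mutation_table(path) == []

    def test_round_trip_exact(self, tmp_path):
        calls = [
            make_call(pos=1000 + i, context=None if i % 2 else "TCG", rescued=bool(i % 3))
            for i in range(10)
        ]
        path = tmp_path / "rt.tsv"
        write_mutation_table(calls, path)
        assert read_mutation_table(path) == calls

    def test_missing_column_names_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("patient_id\tregion_id\nP1\tR1\n")
        with pytest.raises(SchemaError, match="chrom"):
            read_mutation_table(path)

    def test_unparseable_row_reports_line(self, tmp_path):
        calls = [make_call()]
        path = tmp_path / "bad2.tsv"
        write_mutation_table(calls, path)
        text = path.read_text().replace("1000000", "not_a_pos")
        path.write_text(text)
        with pytest.raises(SchemaError, match="line 2"):
            read_mutation_table(path)


VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="gene">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="effect">
##INFO=<ID=POP_AF,Number=1,Type=Float,Description="population AF">
##INFO=<ID=NORMAL_AD,Number=1,Type=Integer,Description="normal alt">
##INFO=<ID=NORMAL_DP,Number=1,Type=Integer,Description="normal depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
##contig=<ID=1,length=249250621>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tR1\tR2
1\t5000\t.\tC\tA,T\t.\tPASS\tGENE=TP53;EFFECT=nonsilent;POP_AF=0.0;NORMAL_AD=0;NORMAL_DP=200\tAD:DP\t100,20,5:125\t90,0,30:120
1\t7000\t.\tG\tA\t.\tPASS\tGENE=RB1;EFFECT=silent;POP_AF=0.002;NORMAL_AD=1;NORMAL_DP=150\tAD:DP\t80,40:120\t70,10:80
"""


class TestVcfDialect:
    def test_multiallelic_split_matches_line_oracle(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_TEXT)
        calls = read_mutation_table(path, dialect="vcf", patient_id="P7")

        # independent line-by-line expectation from the fixture text
        expected = []
        for line in VCF_TEXT.splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            alts = f[4].split(",")
            for ai, alt in enumerate(alts):
                for si, sample in enumerate(["R1", "R2"]):
                    ad = [int(x) for x in f[9 + si].split(":")[0].split(",")]
                    expected.append(
                        (f[0], int(f[1]), f[3], alt, sample, ad[0], ad[ai + 1])
                    )
        got = [
            (c.chrom, c.pos, c.ref, c.alt, c.region_id, c.ref_reads, c.alt_reads)
            for c in calls
        ]
        assert got == expected
        assert len(calls) == 6  # 2 ALTs x 2 regions + 1 ALT x 2 regions
        assert all(c.patient_id == "P7" for c in calls)

    def test_info_fields_propagated(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_TEXT)
        calls = read_mutation_table(path, dialect="vcf")
        silent = [c for c in calls if c.gene == "RB1"]
        assert all(c.effect == "silent" for c in silent)
        assert silent[0].population_af == pytest.approx(0.002)
        assert silent[0].normal_depth == 150


class TestSegmentsIO:
    def test_two_disjoint_segments_sorted(self, tmp_path):
        segs = [
            make_segment(start=50_000_001, end=60_000_000),
            make_segment(start=1, end=50_000_000),
        ]
        path = tmp_path / "s.tsv"
        write_segments(segs, path)
        back = read_segments(path)
        assert [s.start for s in back] == [1, 50_000_001]

    def test_major_less_than_minor_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "patient_id\tregion_id\tchrom\tstart\tend\ttotal_cn\tmajor_cn\tminor_cn\n"
            "P1\tR1\t1\t1\t1000\t3.0\t1\t2\n"
        )
        with pytest.raises(ValidationError):
            read_segments(path)

    def test_overlap_rejected_names_pair(self, tmp_path):
        segs = [
            make_segment(start=1, end=50_000_000),
            make_segment(start=40_000_000, end=90_000_000),
        ]
        path = tmp_path / "s.tsv"
        write_segments(segs, path)
        with pytest.raises(ValidationError, match="overlap"):
            read_segments(path)

    def test_ten_segment_round_trip(self, tmp_path):
        segs = [
            make_segment(
                chrom=str(c),
                start=1,
                end=10_000_000,
                total_cn=float(t),
                major_cn=t - 1,
                minor_cn=1,
            )
            for c, t in zip(range(1, 11), [2, 3, 4, 2, 3, 2, 5, 2, 3, 2])
        ]
        path = tmp_path / "s.tsv"
        write_segments(segs, path)
        assert read_segments(path) == sorted(
            segs, key=lambda s: int(s.chrom)
        )


class TestPatientReportIO:
    def _report(self, pid="P1", snv_ith=0.3):
        return PatientReport(
            patient_id=pid,
            n_mutations=380,
            snv_ith=snv_ith,
            cnv_ith=0.485,
            tmb=10.0,
            n_clusters=3,
            tmb_per_cluster=10.0 / 3,
            wgd=True,
            gii=0.25,
        )

    def test_value_lands_in_named_column(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_patient_report(self._report(snv_ith=0.3), path)
        header, row = path.read_text().strip().split("\n")
        cols = dict(zip(header.split("\t"), row.split("\t")))
        assert cols["snv_ith"] == "0.3"

    def test_round_trip_batch(self, tmp_path):
        reports = [self._report(pid=f"P{i}", snv_ith=i / 10) for i in range(5)]
        path = tmp_path / "r.tsv"
        write_patient_report(reports, path)
        assert core_io.read_patient_reports(path) == reports

    def test_empty_batch_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_patient_report([], path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 1
        assert lines[0].split("\t") == list(PatientReport.COLUMNS)


def test_half_open_conversion():
    # BED [999, 1000) is the single 1-based position 1000
    assert from_half_open(999, 1000) == (1000, 1000)
    assert from_half_open(0, 10) == (1, 10)
    with pytest.raises(ValidationError):
        from_half_open(5, 5)
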