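"""I/O round trips, allele recoding, and window selection."""

import numpy as np
import pytest

from cnphase import hapio
from cnphase.hapio import (
    CNVRecord,
    EmptyWindowError,
    HaplotypePanel,
    ParseError,
    Pedigree,
    read_cnv_table,
    read_haplotypes,
    select_window,
)
from cnphase.phaser import DiplotypeCallSet

HAP_TEXT = """\
chrom 1
sample_ids s1 s2
rs1 100 A A C A
rs2 200 G G G T
rs3 300 T C T T
"""


@pytest.fixture
def hap_file(tmp_path):
    p = tmp_path / "panel.hap"
    p.write_text(HAP_TEXT)
    return str(p)


def test_hap_matrix_shape_and_recoding(hap_file):
    panel = read_haplotypes(hap_file)
    assert panel.sample_ids == ["s1", "s2"]
    assert panel.alleles.shape == (4, 3)
    assert panel.n_snps == 3
    # rs1: A major (3 of 4) -> 0, C minor -> 1; columns are s1A s1B s2A s2B
    assert list(panel.alleles[:, 0]) == [0, 0, 1, 0]
    assert list(panel.alleles[:, 1]) == [0, 0, 0, 1]


def test_hap_matrix_round_trip(tmp_path, hap_file):
    panel = read_haplotypes(hap_file)
    out = tmp_path / "out.hap"
    hapio.write_haplotypes(panel, str(out))
    again = read_haplotypes(str(out))
    assert again.sample_ids == panel.sample_ids
    assert np.array_equal(again.alleles, panel.alleles)
    assert np.array_equal(again.snp_positions, panel.snp_positions)


def test_empty_hap_file_is_an_error(tmp_path):
    p = tmp_path / "empty.hap"
    p.write_text("")
    with pytest.raises(ParseError):
        read_haplotypes(str(p))


def test_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.hap"
    p.write_text("sample_ids s1\nrs1 100 0\n")  # needs 2 allele columns
    with pytest.raises(ParseError, match="line 2"):
        read_haplotypes(str(p))


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t0|0\t1|0
1\t200\trs2\tG\tT\t.\tPASS\t.\tGT\t0|1\t0|0
1\t300\trs3\tT\tC\t.\tPASS\t.\tGT\t0/1\t0|0
1\t400\trs4\tA\tG\t.\tPASS\t.\tGT\t1|1\t0|0
1\t500\trs5\tA\tC,G\t.\tPASS\t.\tGT\t1|2\t0|0
1\t600\trs6\tC\tT\t.\tPASS\t.\tGT\t0|1\t1|1
"""


def test_vcf_skips_unphased_and_multiallelic(tmp_path):
    p = tmp_path / "test.vcf"
    p.write_text(VCF_TEXT)
    panel = read_haplotypes(str(p), format="vcf")
    # rs3 (unphased) and rs5 (multiallelic) skipped
    assert panel.snp_ids == ["rs1", "rs2", "rs4", "rs6"]
    assert panel.alleles.shape == (4, 4)
    # VCF positions converted to 0-based
    assert list(panel.snp_positions) == [99, 199, 399, 599]


CNV_TEXT = "cnv_id\tchrom\tstart\tend\ts1\ts2\ncnv1\t1\t100\t200\t2\t3\n"


def test_cnv_table_basic(tmp_path):
    p = tmp_path / "cnv.tsv"
    p.write_text(CNV_TEXT)
    (rec,) = read_cnv_table(str(p))
    assert rec.totals == {"s1": 2, "s2": 3}
    assert (rec.start, rec.end) == (100, 200)


@pytest.mark.parametrize(
    "cell, error",
    [("2.5", ParseError), ("-1", ParseError)],
)
def test_cnv_table_rejects_bad_cells(tmp_path, cell, error):
    p = tmp_path / "cnv.tsv"
    p.write_text(f"cnv_id\tchrom\tstart\tend\ts1\ncnv1\t1\t100\t200\t{cell}\n")
    with pytest.raises(error):
        read_cnv_table(str(p))


def test_cnv_table_missing_cell_flags_individual(tmp_path):
    p = tmp_path / "cnv.tsv"
    p.write_text("cnv_id\tchrom\tstart\tend\ts1\ts2\ncnv1\t1\t100\t200\t.\t2\n")
    (rec,) = read_cnv_table(str(p))
    assert rec.totals["s1"] is None
    assert rec.called_samples() == ["s2"]


def _panel_with_positions(positions):
    n = len(positions)
    return HaplotypePanel(
        sample_ids=["s1"],
        snp_ids=[f"r{i}" for i in range(n)],
        snp_positions=np.array(positions),
        alleles=np.zeros((2, n), dtype=np.uint8),
        chrom="1",
    )


def test_window_arithmetic_onefold_extension():
    panel = _panel_with_positions([7999, 8000, 10500, 13999, 14000])
    cnv = CNVRecord("c", "1", 10000, 12000, {"s1": 2})
    local = select_window(panel, cnv, extension_factor=1.0)
    assert local.window == (8000, 14000)
    assert local.snp_ids == ["r1", "r2", "r3"]


def test_window_f0_keeps_only_snps_inside_cnv():
    panel = _panel_with_positions([9999, 10000, 11999, 12000])
    cnv = CNVRecord("c", "1", 10000, 12000, {"s1": 2})
    local = select_window(panel, cnv, extension_factor=0.0)
    assert local.snp_ids == ["r1", "r2"]


def test_window_monotone_in_extension_factor():
    rng = np.random.default_rng(7)
    panel = _panel_with_positions(sorted(rng.choice(30000, 40, replace=False)))
    cnv = CNVRecord("c", "1", 10000, 12000, {"s1": 2})
    previous: set = set()
    for f in (0.0, 0.5, 1.0, 2.0, 4.0):
        try:
            snps = set(select_window(panel, cnv, extension_factor=f).snp_ids)
        except EmptyWindowError:
            snps = set()
        assert previous <= snps
        previous = snps


def test_empty_window_raises():
    panel = _panel_with_positions([100, 200])
    cnv = CNVRecord("c", "1", 10000, 12000, {"s1": 2})
    with pytest.raises(EmptyWindowError):
        select_window(panel, cnv, extension_factor=0.0)


def test_chromosome_mismatch_raises():
    panel = _panel_with_positions([10500])
    cnv = CNVRecord("c", "2", 10000, 12000, {"s1": 2})
    with pytest.raises(ValueError, match="chromosome"):
        select_window(panel, cnv)


def _call_set():
    return DiplotypeCallSet(
        cnv_id="cnv1",
        sample_ids=["s1", "s2", "s3"],
        pairs={"s1": (1, 1), "s2": (0, 2), "s3": (-1, -1)},
        totals={"s1": 2, "s2": 2, "s3": 4},
        satisfied={"s1": True, "s2": True, "s3": False},
        chosen_k=3,
        n_satisfied=2,
    )


def test_calls_round_trip(tmp_path):
    out = tmp_path / "calls.tsv"
    calls = _call_set()
    hapio.write_calls([calls], str(out))
    (back,) = hapio.read_calls(str(out))
    assert back.pairs == calls.pairs
    assert back.totals == calls.totals
    assert back.satisfied == calls.satisfied
    assert back.chosen_k == calls.chosen_k
    text = out.read_text()
    assert "0\t2\t2\ttrue" in text  # deletion+duplication serialized plainly
    assert "NA\tNA" in text  # unresolved call


def test_pedigree_self_parent_rejected():
    with pytest.raises(ValueError):
        Pedigree([("c1", "c1", "m1")])


def test_pedigree_unknown_sample_rejected():
    ped = Pedigree([("c1", "f1", "m1")])
    with pytest.raises(ValueError, match="f1"):
        ped.validate_against(["c1", "m1"])
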