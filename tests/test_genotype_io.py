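"""Genotype file parsing: format sniffing, 23andMe dialect, VCF conventions."""

import io

import pytest

from medsafecode.errors import FormatError, GenotypeParseError
from medsafecode.fixtures import FixtureSpec, sample_profile, write_23andme, write_vcf
from medsafecode.genotype_io import (
    UNKNOWN,
    GenotypeProfile,
    detect_format,
    parse_23andme,
    parse_vcf,
    restrict_to_panel,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=10>\n"
    "##contig=<ID=16>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def _vcf(tmp_path, records, header=VCF_HEADER):
    path = tmp_path / "in.vcf"
    path.write_text(header + "".join(r + "\n" for r in records))
    return path


# ---------------------------------------------------------------------------
# detect_format


@pytest.mark.parametrize(
    "text, expected",
    [
        ("##fileformat=VCFv4.2\n#CHROM\t...\n", "vcf"),
        ("# generated by a consumer array\nrs1057910\t10\t96741053\tAC\n", "23andme"),
        ("hello world\n", "unknown"),
        ("col1,col2,col3,col4\n", "unknown"),
    ],
)
def test_detect_format(text, expected):
    assert detect_format(io.StringIO(text)) == expected


def test_detect_format_empty_stream_raises():
    with pytest.raises(FormatError):
        detect_format(io.StringIO(""))


# ---------------------------------------------------------------------------
# 23andMe


def test_parse_23andme_basic_calls_and_unknowns():
    text = (
        "# comment\n"
        "rs1057910\t10\t96741053\tAC\n"
        "rs12345\t1\t100\t--\n"
        "rs22\t1\t200\tID\n"
        "i3000001\t1\t300\tAA\n"
    )
    profile = parse_23andme(io.StringIO(text))
    assert profile.calls == {"rs1057910": ("A", "C"), "rs12345": UNKNOWN, "rs22": UNKNOWN}
    assert profile.source_format == "23andme"


def test_parse_23andme_reverse_orientation_complements():
    profile = parse_23andme(io.StringIO("rs1057910\t10\t96741053\tAC\n"), orientation="reverse")
    assert profile.calls["rs1057910"] == ("G", "T")


def test_strand_flip_is_an_involution():
    spec = FixtureSpec(n_markers=30, seed=5, missing_rate=0.1)
    from medsafecode.fixtures import generate_synthetic_kb

    kb = generate_synthetic_kb(spec)
    profile = sample_profile(kb, spec)
    buf = io.StringIO()
    write_23andme(profile, kb, buf)
    forward = parse_23andme(io.StringIO(buf.getvalue()), orientation="forward")
    flipped_once = parse_23andme(io.StringIO(buf.getvalue()), orientation="reverse")
    # complement the complemented calls: must equal the forward parse
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    twice = {
        rsid: (None if call is UNKNOWN else tuple(sorted(comp[b] for b in call)))
        for rsid, call in flipped_once.calls.items()
    }
    assert twice == forward.calls


def test_parse_23andme_single_base_autosomal_vs_sex_chromosome(caplog):
    text = "rs1\t7\t100\tA\nrs2\tX\t200\tG\n"
    with caplog.at_level("WARNING", logger="medsafecode.genotype_io"):
        profile = parse_23andme(io.StringIO(text))
    assert profile.calls == {"rs1": UNKNOWN, "rs2": ("G", "G")}
    assert "single-base" in caplog.text


def test_parse_23andme_malformed_line_reports_line_number():
    with pytest.raises(GenotypeParseError, match="line 2"):
        parse_23andme(io.StringIO("rs1\t1\t100\tAA\nrs2\t1\t200\n"))


# ---------------------------------------------------------------------------
# VCF


def test_parse_vcf_het_by_rsid(paper_kb, tmp_path):
    path = _vcf(tmp_path, ["10\t96741053\trs1057910\tA\tC\t.\t.\t.\tGT\t0/1"])
    profile = parse_vcf(path, paper_kb)
    assert profile.calls["rs1057910"] == ("A", "C")


def test_parse_vcf_zero_records_means_all_reference(paper_kb, tmp_path):
    profile = parse_vcf(_vcf(tmp_path, []), paper_kb)
    assert profile.calls == {m.rsid: (m.reference, m.reference) for m in paper_kb.markers}
    assert profile.unknown_count() == 0


def test_parse_vcf_phased_homalt_and_position_fallback(paper_kb, tmp_path):
    # ID missing: matched by chromosome+position
    path = _vcf(tmp_path, ["16\t31107689\t.\tC\tT\t.\t.\t.\tGT\t1|1"])
    profile = parse_vcf(path, paper_kb)
    assert profile.calls["rs9923231"] == ("T", "T")


def test_parse_vcf_nocall_and_halfcall_set_unknown(paper_kb, tmp_path, caplog):
    path = _vcf(
        tmp_path,
        [
            "10\t96741053\trs1057910\tA\tC\t.\t.\t.\tGT\t./.",
            "16\t31107689\trs9923231\tC\tT\t.\t.\t.\tGT\t0/.",
        ],
    )
    with caplog.at_level("WARNING", logger="medsafecode.genotype_io"):
        profile = parse_vcf(path, paper_kb)
    assert profile.calls["rs1057910"] is UNKNOWN
    assert profile.calls["rs9923231"] is UNKNOWN
    assert "half-call" in caplog.text


def test_parse_vcf_disallowed_alt_and_indel_become_unknown(paper_kb, tmp_path, caplog):
    path = _vcf(
        tmp_path,
        [
            "10\t96741053\trs1057910\tA\tG\t.\t.\t.\tGT\t1/1",  # G not allowed
            "16\t31107689\trs9923231\tC\tCTT\t.\t.\t.\tGT\t0/1",  # indel allele
        ],
    )
    with caplog.at_level("WARNING", logger="medsafecode.genotype_io"):
        profile = parse_vcf(path, paper_kb)
    assert profile.calls["rs1057910"] is UNKNOWN
    assert profile.calls["rs9923231"] is UNKNOWN


def test_parse_vcf_off_panel_records_are_ignored(paper_kb, tmp_path):
    path = _vcf(tmp_path, ["10\t12345\trs777\tA\tC\t.\t.\t.\tGT\t1/1"])
    profile = parse_vcf(path, paper_kb)
    assert "rs777" not in profile.calls
    assert profile.unknown_count() == 0


def test_parse_vcf_multi_sample_is_rejected(paper_kb, tmp_path):
    header = VCF_HEADER.replace("\tS1\n", "\tS1\tS2\n")
    path = _vcf(tmp_path, ["10\t96741053\trs1057910\tA\tC\t.\t.\t.\tGT\t0/1\t0/0"], header)
    with pytest.raises(GenotypeParseError, match="single-sample"):
        parse_vcf(path, paper_kb)


def test_parse_vcf_headerless_file_is_rejected(paper_kb, tmp_path):
    path = tmp_path / "broken.vcf"
    path.write_text("10\t96741053\trs1057910\tA\tC\t.\t.\t.\tGT\t0/1\n")
    with pytest.raises(GenotypeParseError):
        parse_vcf(path, paper_kb)


def test_parse_vcf_accepts_text_stream(paper_kb):
    stream = io.StringIO(VCF_HEADER + "10\t96741053\trs1057910\tA\tC\t.\t.\t.\tGT\t0/1\n")
    profile = parse_vcf(stream, paper_kb)
    assert profile.calls["rs1057910"] == ("A", "C")


# ---------------------------------------------------------------------------
# restrict_to_panel


def test_restrict_to_panel_exact_keys_and_idempotence(paper_kb):
    big = GenotypeProfile(calls={"rs1057910": ("A", "C"), "rs777": ("G", "G")})
    small = restrict_to_panel(big, paper_kb)
    assert set(small.calls) == set(paper_kb.panel)
    assert small.calls["rs1057910"] == ("A", "C")
    assert small.calls["rs9923231"] is UNKNOWN
    assert restrict_to_panel(small, paper_kb).calls == small.calls


def test_restrict_to_panel_empty_profile_goes_all_unknown(paper_kb):
    small = restrict_to_panel(GenotypeProfile(calls={}), paper_kb)
    assert all(c is UNKNOWN for c in small.calls.values())


# ---------------------------------------------------------------------------
# writer/parser round trips


def test_round_trips_both_dialects(paper_kb, tmp_path):
    profile = GenotypeProfile(
        calls={
            "rs1057910": ("A", "C"),
            "rs1057911": UNKNOWN,
            "rs1799853": ("C", "C"),
            "rs2256871": ("G", "G"),
            "rs9923231": ("C", "T"),
        }
    )
    tsv = io.StringIO()
    write_23andme(profile, paper_kb, tsv)
    assert parse_23andme(io.StringIO(tsv.getvalue())).calls == profile.calls

    vcf_path = tmp_path / "out.vcf"
    with vcf_path.open("w") as fh:
        write_vcf(profile, paper_kb, fh)
    assert parse_vcf(vcf_path, paper_kb).calls == profile.calls
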