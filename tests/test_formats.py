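"""File-format contracts: parsing, validation errors, round trips."""

import gzip

import pytest
from hypothesis import given
from hypothesis import strategies as st

from motifsnps.errors import FormatError
from motifsnps.formats import (GenomicRegion, GenotypedMarker, LdRecord,
                               MaskedSequence, SnpCatalogue, SnpLocus,
                               normalize_chrom, read_bed, read_hapmap,
                               read_ld, read_map, read_masked_fasta,
                               read_motif, write_bed, write_fasta,
                               write_hapmap, write_ld, write_map)


# --- FASTA ---------------------------------------------------------------

def test_masked_fasta_basic(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">chr1 extra tokens\nacgRTA\n>c\n")
    records = read_masked_fasta(p)
    assert [(r.chrom, r.seq) for r in records] == [("1", "ACGRTA"), ("c", "")]
    assert records[0].snp_positions() == [4]
    assert records[1].snp_positions() == []


def test_masked_fasta_rejects_bad_alphabet_with_line_number(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">chr1\nACGT\nACZT\n")
    with pytest.raises(FormatError, match=r":3.*'Z'"):
        read_masked_fasta(p)


def test_masked_fasta_empty_file_and_headerless_sequence(tmp_path):
    empty = tmp_path / "e.fa"
    empty.write_text("")
    with pytest.raises(FormatError, match="empty"):
        read_masked_fasta(empty)
    headerless = tmp_path / "h.fa"
    headerless.write_text("ACGT\n")
    with pytest.raises(FormatError, match="header"):
        read_masked_fasta(headerless)


# --- BED -----------------------------------------------------------------

def test_bed_coordinate_conversion_and_defaults(tmp_path):
    p = tmp_path / "r.bed"
    p.write_text("chr1\t9\t12\tpeak1\t5\nchr2\t0\t6\n")
    regions = read_bed(p)
    assert regions[0] == GenomicRegion("1", 10, 12, "peak1", 5.0)
    assert regions[1] == GenomicRegion("2", 1, 6, "", 1.0)  # default score 1


@pytest.mark.parametrize("line,msg", [
    ("chr1\t5\t5", "empty or inverted"),
    ("chr1\t5", "3-5 columns"),
    ("chr1\t1\t2\tx\t3\textra", "3-5 columns"),
    ("chr1\tten\t20", "non-numeric"),
])
def test_bed_rejects_malformed_lines(tmp_path, line, msg):
    p = tmp_path / "r.bed"
    p.write_text(line + "\n")
    with pytest.raises(FormatError, match=msg):
        read_bed(p)


# --- HapMap catalogue ----------------------------------------------------

def test_hapmap_lookup_and_missing(tmp_path):
    p = tmp_path / "h.txt"
    p.write_text("chr1 1234 rs42\n1 99 rs7\n")
    cat = read_hapmap(p)
    assert cat.lookup("chr1", 1234) == "rs42"
    assert cat.lookup("1", 1234) == "rs42"      # chr prefix normalised
    assert cat.lookup("1", 4321) is None
    assert cat.in_interval("1", 99, 1234) == [SnpLocus("1", 99, "rs7"),
                                              SnpLocus("1", 1234, "rs42")]


def test_hapmap_duplicate_position_keeps_first_and_warns(tmp_path, caplog):
    p = tmp_path / "h.txt"
    p.write_text("1 10 rsA\n1 10 rsB\n")
    with caplog.at_level("WARNING"):
        cat = read_hapmap(p)
    assert cat.lookup("1", 10) == "rsA"
    assert any("duplicate" in rec.message for rec in caplog.records)


def test_hapmap_rejects_wrong_column_count(tmp_path):
    p = tmp_path / "h.txt"
    p.write_text("1 10 rsA extra\n")
    with pytest.raises(FormatError, match=":1"):
        read_hapmap(p)


# --- MAP -----------------------------------------------------------------

def test_map_reads_four_columns(tmp_path):
    p = tmp_path / "m.map"
    p.write_text("1 rs42 0 1234\n")
    assert read_map(p) == [GenotypedMarker("1", "rs42", 0.0, 1234)]


def test_map_rejects_wrong_column_count(tmp_path):
    p = tmp_path / "m.map"
    p.write_text("1 rs42 0 1234 extra\n")
    with pytest.raises(FormatError, match="exactly four"):
        read_map(p)


def test_map_empty_file_is_valid(tmp_path):
    p = tmp_path / "m.map"
    p.write_text("")
    assert read_map(p) == []


# --- LD ------------------------------------------------------------------

def _write_gz(path, text):
    with gzip.open(path, "wt") as fh:
        fh.write(text)


def test_ld_parses_hapmap_dialect(tmp_path):
    p = tmp_path / "ld.gz"
    _write_gz(p, "1234 5678 CEU rs42 rs99 1.0 0.93 12.1\n")
    rec, = read_ld(p, "chr7")
    assert rec == LdRecord("7", 1234, 5678, "CEU", "rs42", "rs99", 1.0, 0.93, 12.1)
    assert rec.partner_of("rs42") == ("rs99", 5678)
    assert rec.partner_of("rs99") == ("rs42", 1234)
    assert rec.partner_of("rsX") is None


def test_ld_rejects_out_of_range_r2_and_bad_gzip(tmp_path):
    p = tmp_path / "ld.gz"
    _write_gz(p, "1 2 CEU a b 1.0 1.2 3\n")
    with pytest.raises(FormatError, match="r2"):
        read_ld(p, "1")
    notgz = tmp_path / "no.gz"
    notgz.write_text("plain text\n")
    with pytest.raises(OSError):
        read_ld(notgz, "1")


def test_ld_empty_gzip_yields_empty_stream(tmp_path):
    p = tmp_path / "ld.gz"
    _write_gz(p, "")
    assert read_ld(p, "1") == []


# --- motif ---------------------------------------------------------------

def test_motif_file_single_pattern_only(tmp_path):
    p = tmp_path / "m.txt"
    p.write_text("RGnACA gr-half-site\n")
    motif = read_motif(p)
    assert motif.sequence == "RGNACA" and motif.label == "gr-half-site"
    p.write_text("AGGTCA\nRGKKSA\n")
    with pytest.raises(FormatError, match="one motif"):
        read_motif(p)


# --- round trips ---------------------------------------------------------

def test_fasta_round_trip(tmp_path):
    records = [MaskedSequence("1", "ACGT" * 40 + "R"), MaskedSequence("2", "")]
    path = tmp_path / "rt.fa"
    write_fasta(records, path)
    assert read_masked_fasta(path) == records


@given(st.lists(
    st.tuples(st.sampled_from(["1", "2", "X"]),
              st.integers(0, 10_000), st.integers(1, 500),
              st.sampled_from(["", "peak"]), st.integers(0, 50)),
    min_size=1, max_size=20))
def test_bed_round_trip(tmp_path_factory, rows):
    regions = [GenomicRegion(c, s + 1, s + ln, n, float(sc))
               for c, s, ln, n, sc in rows]
    path = tmp_path_factory.mktemp("rt") / "rt.bed"
    write_bed(regions, path)
    back = read_bed(path)
    assert [(r.chrom, r.start, r.end, r.score) for r in back] == \
           [(r.chrom, r.start, r.end, r.score) for r in regions]


def test_hapmap_map_ld_round_trips(tmp_path):
    cat = SnpCatalogue([SnpLocus("1", 5, "rs1"), SnpLocus("2", 9, "rs2")])
    hp = tmp_path / "h.txt"
    write_hapmap(cat, hp)
    assert list(read_hapmap(hp).loci()) == list(cat.loci())

    markers = [GenotypedMarker("1", "rs1", 0.0, 5),
               GenotypedMarker("2", "rs2", 1.5, 9)]
    mp = tmp_path / "m.map"
    write_map(markers, mp)
    assert read_map(mp) == markers

    records = [LdRecord("1", 5, 9, "CEU", "rs1", "rs2", 1.0, 0.85, 11.0)]
    lp = tmp_path / "ld.gz"
    write_ld(records, lp)
    assert read_ld(lp, "1") == records


def test_normalize_chrom():
    assert normalize_chrom("chr1") == "1"
    assert normalize_chrom("CHRX") == "X"
    assert normalize_chrom("7") == "7"
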