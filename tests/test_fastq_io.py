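"""FASTQ scanning, reads extraction, sampling and fingerprinting."""

import gzip

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmffrc.errors import MalformedFastqError
from pmffrc.fastq_io import (
    ReadsStream,
    extract_reads_stream,
    fingerprint,
    read_reads_file,
    sample_record_groups,
    scan_fastq,
    write_reads_file,
)

from conftest import write_fastq

reads_lists = st.lists(
    st.text(alphabet="ACGTN", min_size=1, max_size=30), min_size=1, max_size=20
)


class TestScan:
    def test_counts_records_and_bases(self, fastq_writer):
        f = scan_fastq(fastq_writer("a.fastq", ["ACGT", "GGGG"]))
        assert (f.n_records, f.total_bases, f.mean_read_length) == (2, 8, 4.0)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        f = scan_fastq(p)
        assert (f.n_records, f.total_bases, f.mean_read_length) == (0, 0, 0.0)

    def test_gzip_transparent(self, tmp_path, fastq_writer):
        plain = fastq_writer("a.fastq", ["ACGTACGT", "TTTT"])
        gz = tmp_path / "a.fastq.gz"
        gz.write_bytes(gzip.compress(plain.read_bytes()))
        assert scan_fastq(gz).n_records == 2
        assert extract_reads_stream(gz).reads == ("ACGTACGT", "TTTT")

    @pytest.mark.parametrize(
        "lines,fragment",
        [
            ("@r0\nACGT\n+\nIIII\n@r1\nACGT\nIIII\n", "not a multiple of 4"),
            ("ACGT\nACGT\n+\nIIII\n", "must start with '@'"),
            ("@r0\nACGT\nACGT\nIIII\n", "separator line"),
            ("@r0\nACGT\n+\nII\n", "quality length"),
        ],
    )
    def test_malformed_rejected_not_truncated(self, tmp_path, lines, fragment):
        p = tmp_path / "bad.fastq"
        p.write_text(lines)
        with pytest.raises(MalformedFastqError, match=fragment):
            scan_fastq(p)


class TestExtract:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("acgtn", "ACGTN"),  # case normalization
            ("ACRGT", "ACNGT"),  # non-ACGTN maps to N
            ("ACGT", "ACGT"),
        ],
    )
    def test_normalization(self, fastq_writer, raw, expected):
        stream = extract_reads_stream(fastq_writer("a.fastq", [raw]))
        assert stream.reads == (expected,)

    def test_order_preserved(self, fastq_writer):
        reads = ["AAA", "CCC", "GGG"]
        assert extract_reads_stream(fastq_writer("a.fastq", reads)).reads == tuple(reads)

    @given(reads=reads_lists)
    def test_roundtrip_and_length_agreement(self, tmp_path, reads):
        """scan/extract agree, and write-back of a reads stream is the identity."""
        p = write_fastq(tmp_path / "h.fastq", reads)
        scanned = scan_fastq(p)
        stream = extract_reads_stream(p)
        assert len(stream) == scanned.n_records == len(reads)
        assert sum(map(len, stream.reads)) == scanned.total_bases
        back = write_reads_file(stream, tmp_path / "h.reads")
        assert read_reads_file(back).reads == stream.reads


class TestSampling:
    def test_output_count_is_v_times_x(self, fastq_writer, tmp_path):
        files = [
            scan_fastq(fastq_writer(f"f{i}.fastq", ["ACGT"] * (10 + i)), index=i)
            for i in range(3)
        ]
        out = sample_record_groups(files, x=5, seed=1, out_path=tmp_path / "pre.fastq")
        assert scan_fastq(out).n_records == 15

    def test_with_replacement_when_x_exceeds_records(self, fastq_writer, tmp_path):
        files = [scan_fastq(fastq_writer("f.fastq", ["ACGT", "GGGG"]))]
        out = sample_record_groups(files, x=7, seed=1, out_path=tmp_path / "pre.fastq")
        assert scan_fastq(out).n_records == 7

    def test_deterministic_per_seed(self, fastq_writer, tmp_path):
        files = [scan_fastq(fastq_writer("f.fastq", ["ACGT"] * 20))]
        a = sample_record_groups(files, x=5, seed=9, out_path=tmp_path / "a.fastq")
        b = sample_record_groups(files, x=5, seed=9, out_path=tmp_path / "b.fastq")
        assert a.read_bytes() == b.read_bytes()

    def test_single_record_identity(self, fastq_writer, tmp_path):
        src = fastq_writer("one.fastq", ["ACGTACGT"])
        files = [scan_fastq(src)]
        out = sample_record_groups(files, x=1, seed=0, out_path=tmp_path / "o.fastq")
        assert out.read_bytes() == src.read_bytes()

    def test_records_kept_intact(self, fastq_writer, tmp_path):
        src = fastq_writer(
            "q.fastq", ["ACGT", "TTTT"], quals=["!!XX", "ABCD"], headers=["@a desc", "@b"]
        )
        files = [scan_fastq(src)]
        out = sample_record_groups(files, x=2, seed=0, out_path=tmp_path / "o.fastq")
        assert out.read_text() == src.read_text()  # header+qual survive sampling

    def test_errors(self, fastq_writer, tmp_path):
        with pytest.raises(ValueError, match="empty collection"):
            sample_record_groups([], x=1, seed=0, out_path=tmp_path / "o.fastq")
        empty = tmp_path / "e.fastq"
        empty.write_text("")
        files = [scan_fastq(empty)]
        with pytest.raises(ValueError, match="zero records"):
            sample_record_groups(files, x=1, seed=0, out_path=tmp_path / "o.fastq")


class TestFingerprint:
    def test_equal_streams_equal_digests(self):
        a = ReadsStream(0, ("ACGT", "GGGG"))
        b = ReadsStream(3, ("ACGT", "GGGG"))
        assert fingerprint(a).digest == fingerprint(b).digest

    def test_single_base_change_differs(self):
        a = ReadsStream(0, ("ACGT", "GGGG"))
        b = ReadsStream(0, ("ACGT", "GGGA"))
        assert fingerprint(a).digest != fingerprint(b).digest

    def test_empty_stream_defined(self):
        fp = fingerprint(ReadsStream(0, ()))
        assert len(fp.digest) == 64  # sha-256 hex of the empty string
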