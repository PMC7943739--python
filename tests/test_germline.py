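"""Germline reference loading, mismatch distances and nearest neighbors."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ighvrare.germline import (
    GermlineAllele,
    GermlineDatabase,
    load_germline_fasta,
    nearest_neighbor,
    pairwise_mismatch,
    write_germline_fasta,
)


def _write(tmp_path, text, name="ref.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoading:
    def test_counts_and_segments(self, tmp_path):
        p = _write(tmp_path, (
            ">IGHV1-2*02\nACGTACGT\n>IGHV1-2*04\nACGAACGT\n"
            ">IGHJ6*02\nTTTTGGTT\n>IGHJ6*03\nTTATGGTT\n"))
        db = load_germline_fasta(p)
        assert len(db) == 4
        assert db.segment_counts() == {"V": 2, "J": 2}

    def test_imgt_pipe_header_and_gaps(self, tmp_path):
        p = _write(tmp_path,
                   ">X|IGHV1-2*02|Homo sapiens|F|V-REGION\nAC..GT.ACG\n")
        db = load_germline_fasta(p)
        a = db["IGHV1-2*02"]
        assert a.sequence_ungapped == "ACGTACG"
        assert a.sequence_gapped == "AC..GT.ACG"

    def test_gzip_round_trip(self, tmp_path, db):
        p = tmp_path / "ref.fasta.gz"
        write_germline_fasta(db, p)
        with gzip.open(p, "rt") as fh:
            assert fh.read(1) == ">"
        loaded = load_germline_fasta(p)
        assert sorted(loaded.names) == sorted(db.names)
        # anchors survive the header round trip
        assert loaded["IGHJ6*02"].anchor_offset == db["IGHJ6*02"].anchor_offset

    def test_duplicate_name_rejected(self, tmp_path):
        p = _write(tmp_path, ">IGHV1-2*05\nACGT\n>IGHV1-2*05\nACGT\n")
        with pytest.raises(ValueError, match="IGHV1-2\\*05"):
            load_germline_fasta(p)

    def test_bad_character_rejected(self, tmp_path):
        p = _write(tmp_path, ">IGHV1-2*05\nACXT\n")
        with pytest.raises(ValueError, match="non-ACGT"):
            load_germline_fasta(p)

    def test_unparseable_header_names_record(self, tmp_path):
        p = _write(tmp_path, ">IGHV1-2*02\nACGT\n>garbage\nACGT\n")
        with pytest.raises(ValueError, match="record 2"):
            load_germline_fasta(p)

    def test_gapped_consistency_enforced(self):
        with pytest.raises(ValueError, match="gapped"):
            GermlineAllele("IGHV1-2*02", "ACGT", sequence_gapped="A..CGG")


class TestPairwiseMismatch:
    def test_identity_is_zero(self):
        a = GermlineAllele("IGHV1-2*02", "ACGTACGT")
        assert pairwise_mismatch(a, a) == (0, [])

    def test_toy_pair_positions(self):
        a = GermlineAllele("IGHV1-2*02", "ACGTACGT")
        b = GermlineAllele("IGHV1-2*04", "ACGAACGA")
        count, pos = pairwise_mismatch(a, b)
        assert count == 2
        assert pos == [4, 8]

    def test_near_identical_allele_pair(self, db):
        # emulates an allele pair differing at a single coding position
        count, _ = pairwise_mismatch(db["IGHV7-4-1*01"], db["IGHV7-4-1*02"])
        assert count == 1

    def test_gapped_positions_are_imgt(self):
        a = GermlineAllele("IGHV1-2*02", "ACGT", sequence_gapped="AC..GT")
        b = GermlineAllele("IGHV1-2*04", "ACGA", sequence_gapped="AC..GA")
        count, pos = pairwise_mismatch(a, b)
        assert (count, pos) == (1, [6])  # 1-based gapped coordinate

    def test_segment_mismatch_rejected(self, db):
        with pytest.raises(ValueError, match="segment"):
            pairwise_mismatch(db["IGHV1-2*02"], db["IGHJ6*02"])

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60),
           st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_zero_iff_identical(self, s1, s2):
        a = GermlineAllele("IGHV1-2*02", s1)
        b = GermlineAllele("IGHV1-2*04", s2)
        ab, _ = pairwise_mismatch(a, b)
        ba, _ = pairwise_mismatch(b, a)
        assert ab == ba
        span = min(len(s1), len(s2))
        assert (ab == 0) == (s1[:span] == s2[:span])


class TestNearestNeighbor:
    def test_construction(self):
        base = "A" * 40
        db = GermlineDatabase([
            GermlineAllele("IGHV5-1*01", base),
            GermlineAllele("IGHV5-1*02", base[:-1] + "C"),
            GermlineAllele("IGHV5-1*03", "C" * 5 + base[5:]),
        ])
        assert nearest_neighbor(db["IGHV5-1*01"], db) == ("IGHV5-1*02", 1)

    def test_tie_broken_lexicographically(self):
        db = GermlineDatabase([
            GermlineAllele("IGHV9-1*03", "AAAA"),
            GermlineAllele("IGHV9-1*02", "AAAC"),
            GermlineAllele("IGHV9-1*01", "AACA"),
        ])
        name, dist = nearest_neighbor(db["IGHV9-1*03"], db)
        assert (name, dist) == ("IGHV9-1*01", 1)

    def test_singleton_segment_rejected(self):
        db = GermlineDatabase([GermlineAllele("IGHV5-1*01", "ACGT")])
        with pytest.raises(ValueError):
            nearest_neighbor(db["IGHV5-1*01"], db)

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        alleles = [
            GermlineAllele(f"IGHV5-1*{i:02d}",
                           "".join("ACGT"[b] for b in rng.integers(0, 4, 50)))
            for i in range(1, 21)
        ]
        db = GermlineDatabase(alleles)
        for a in alleles:
            name, dist = nearest_neighbor(a, db)
            dists = {b.name: pairwise_mismatch(a, b)[0]
                     for b in alleles if b.name != a.name}
            assert dist == min(dists.values())
            best = min(d for d in dists.values())
            assert name == min(n for n, d in dists.items() if d == best)
            # nearest_neighbor distance is a lower bound on every pair
            assert all(dist <= d for d in dists.values())
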