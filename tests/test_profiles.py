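"""CDR3 profiles, hotspot motif scanning, focal-codon substitution."""

import re
from math import isclose

import numpy as np
import pandas as pd
import pytest

import ighvrare as iv
from ighvrare.profiles import (
    cdr3_profile,
    focal_codon_profile,
    hotspot_context,
    hotspot_scan,
    imgt_codon_to_ungapped_offset,
)


def _frame(lengths, productive=None, allele="IGHV1-2*05"):
    productive = productive or [(l % 3 == 0) for l in lengths]
    return pd.DataFrame({
        "v_call": allele, "v_unique": True,
        "junction_length": [l + 6 for l in lengths],
        "cdr3_length": lengths,
        "productive": productive,
    })


class TestCdr3Profile:
    def test_in_frame_fraction(self):
        prof = cdr3_profile(_frame([42, 42, 45, 44]), "IGHV1-2*05")
        assert prof.frac_in_frame == 0.75
        assert prof.histogram == {42: 2, 44: 1, 45: 1}

    def test_empty_profile_flagged(self):
        prof = cdr3_profile(_frame([]), "IGHV1-2*05")
        assert prof.empty

    def test_all_productive_simulation(self, db):
        from ighvrare.simulate import HaplotypeSpec, SubjectSpec
        spec = SubjectSpec(
            "t", (HaplotypeSpec("H1", {"IGHV1-2*02": 1.0}, "IGHJ6*02"),
                  HaplotypeSpec("H2", {"IGHV1-3*01": 1.0}, "IGHJ6*03")),
            n_reads=400, passenger_fraction=0.0, seed=8)
        reads, _ = iv.simulate_repertoire(spec, db)
        ann = iv.annotate_sequences([r.read_id for r in reads],
                                    [r.sequence for r in reads], db)
        prof = cdr3_profile(ann[ann.flag == ""], "IGHV1-2*02")
        assert prof.frac_in_frame == 1.0

    def test_passenger_heavy_profile(self, db):
        # a mostly out-of-frame allele profile mirrors a passenger allele
        from ighvrare.simulate import HaplotypeSpec, SubjectSpec
        target = 0.86
        spec = SubjectSpec(
            "t", (HaplotypeSpec("H1", {"IGHV1-3*02": 1.0}, "IGHJ6*02"),
                  HaplotypeSpec("H2", {"IGHV1-3*02": 1.0}, "IGHJ6*03")),
            n_reads=3000, passenger_fraction=target, seed=8)
        reads, _ = iv.simulate_repertoire(spec, db)
        ann = iv.annotate_sequences([r.read_id for r in reads],
                                    [r.sequence for r in reads], db)
        prof = cdr3_profile(ann, "IGHV1-3*02")
        sd = np.sqrt(target * (1 - target) / prof.n_reads)
        assert abs(prof.frac_in_frame - (1 - target)) < 3 * sd


def _oracle(seq, pos):
    """Regex expansion over all literal motif instances."""
    pats = {"RGYW": "[AG]G[CT][AT]", "WRCY": "[AT][AG]C[CT]",
            "WA": "[AT]A", "TA": "TA"}
    hit = False
    for pat in pats.values():
        for m in re.finditer(f"(?=({pat}))", seq):
            if m.start() <= pos < m.start() + len(m.group(1)):
                hit = True
    return hit


class TestHotspotScan:
    def test_rgyw_example(self):
        flags = hotspot_scan("AGCTA", 1)
        assert flags["RGYW"] and flags["any"]

    def test_no_motif_possible(self):
        assert not hotspot_scan("GGGG", 2)["any"]

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            hotspot_scan("ACGT", 7)

    def test_agrees_with_regex_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 50))
            pos = int(rng.integers(0, 50))
            assert hotspot_scan(seq, pos)["any"] == _oracle(seq, pos)

    def test_reverse_complement_mirror(self):
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(7)
        for _ in range(100):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 30))
            rc = seq.translate(comp)[::-1]
            for pos in range(len(seq)):
                f = hotspot_scan(seq, pos)
                g = hotspot_scan(rc, len(seq) - 1 - pos)
                # WRCY is the reverse-complement partner of RGYW
                assert f["RGYW"] == g["WRCY"]


class TestFocalCodon:
    def test_imgt_codon_mapping_through_gaps(self, db):
        a = db["IGHV7-4-1*01"]
        # IMGT codon 104 is the 2nd-CYS anchor
        assert imgt_codon_to_ungapped_offset(a, 104) == a.anchor_offset

    def test_no_shm_means_no_substitution(self, db):
        from ighvrare.cohorts import focal_codon_subject
        spec = focal_codon_subject(seed=3, n_reads=400, shm_rate=0.0)
        reads, _ = iv.simulate_repertoire(spec, db)
        ann = iv.annotate_sequences([r.read_id for r in reads],
                                    [r.sequence for r in reads], db)
        prof = focal_codon_profile(ann, "IGHV7-4-1*01", 92, db,
                                   min_mutations=0)
        assert prof.frac_substituted == 0.0
        assert prof.germline_residue == "C"

    def test_serine_substitution_counted(self, db):
        a = db["IGHV7-4-1*01"]
        off = imgt_codon_to_ungapped_offset(a, 92)
        seq = a.sequence_ungapped
        mutated = seq[:off] + "AGT" + seq[off + 3:]  # TGT(Cys) -> AGT(Ser)
        read = mutated + "GGGGGGGGGGGG" + db["IGHJ6*02"].sequence_ungapped
        ann = iv.annotate_sequences(["r"], [read], db)
        assert ann.iloc[0].productive
        prof = focal_codon_profile(ann, "IGHV7-4-1*01", 92, db,
                                   min_mutations=1)
        assert prof.residue_counts == {"S": 1}
        assert prof.frac_substituted == 1.0

    def test_productive_reads_never_stop_at_focal_codon(self, db):
        from ighvrare.cohorts import focal_codon_subject
        spec = focal_codon_subject(seed=5, n_reads=1500)
        reads, _ = iv.simulate_repertoire(spec, db)
        ann = iv.annotate_sequences([r.read_id for r in reads],
                                    [r.sequence for r in reads], db)
        prof = focal_codon_profile(ann, "IGHV7-4-1*01", 92, db,
                                   min_mutations=1)
        assert "*" not in prof.residue_counts
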