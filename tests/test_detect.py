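"""Expression accounting, occupancy, background nulls, carrier calls and
the statistical contrasts."""

from math import comb, isclose

import numpy as np
import pandas as pd
import pytest

from ighvrare.detect import (
    AlleleExpressionRecord,
    BackgroundModel,
    DetectionCall,
    OccupancyRecord,
    analyze_cohort,
    background_null,
    cohort_summary,
    cosegregation,
    detect,
    expression_frequency,
    fold_difference,
    occupancy,
)
from ighvrare.haplotype import HaplotypeAssignment
from ighvrare.stats import mann_whitney_one_sided


def _ann(n_allele, n_total, allele="IGHV1-2*05"):
    rows = [{"v_call": allele, "v_unique": True, "j_call": "", "j_unique": False}
            for _ in range(n_allele)]
    rows += [{"v_call": "IGHV1-2*02", "v_unique": True, "j_call": "",
              "j_unique": False} for _ in range(n_total - n_allele)]
    return pd.DataFrame(rows)


class TestExpressionFrequency:
    def test_zero_case(self):
        rec = expression_frequency(_ann(0, 1000), "IGHV1-2*05", "s")
        assert rec.n_unique == 0 and rec.frequency == 0.0

    def test_frequency_is_over_file_total(self):
        # 184 unique reads among 200,000 -> 0.092%
        rec = expression_frequency(_ann(184, 200), "IGHV1-2*05", "s",
                                   n_total=200_000)
        assert isclose(rec.frequency_pct, 0.092)

    def test_partition_bound(self):
        df = _ann(30, 100)
        n = sum(expression_frequency(df, a).n_unique
                for a in ("IGHV1-2*05", "IGHV1-2*02", "IGHV1-2*04"))
        assert n <= len(df)

    def test_empty_file_rejected(self):
        with pytest.raises(ValueError):
            expression_frequency(pd.DataFrame({"v_call": [], "v_unique": []}),
                                 "IGHV1-2*05", n_total=0)


def _rec(allele, freq, call=None, sid="s", n_total=100_000):
    hap = None
    if call is not None:
        n = 50
        hap = {"H1": HaplotypeAssignment(allele, n, 0, "H1"),
               "H2": HaplotypeAssignment(allele, 0, n, "H2"),
               "BOTH": HaplotypeAssignment(allele, n, n, "BOTH")}[call]
    return AlleleExpressionRecord(sid, allele, round(freq * n_total), n_total,
                                  hap)


class TestOccupancy:
    def test_two_majors_opposite_haplotypes(self):
        occ = occupancy([_rec("IGHV1-2*02", 0.02, "H1"),
                         _rec("IGHV1-2*04", 0.01, "H2"),
                         _rec("IGHV1-2*05", 0.0001)], "IGHV1-2")
        assert occ.slots_occupied == 2
        assert occ.major_alleles == ["IGHV1-2*02", "IGHV1-2*04"]

    def test_homozygous_both_counts_two_slots(self):
        occ = occupancy([_rec("IGHV1-3*01", 0.02, "BOTH")], "IGHV1-3")
        assert occ.slots_occupied == 2

    def test_single_major_leaves_open_slot(self):
        occ = occupancy([_rec("IGHV1-2*02", 0.02, "H1")], "IGHV1-2")
        assert occ.slots_occupied == 1
        assert occ.open_slot_haplotype == "H2"

    def test_no_haplotype_context_unknown_unless_two_majors(self):
        occ = occupancy([_rec("IGHV1-2*02", 0.02)], "IGHV1-2",
                        heterozygous=False)
        assert occ.slots_occupied is None
        occ2 = occupancy([_rec("IGHV1-2*02", 0.02), _rec("IGHV1-2*04", 0.01)],
                         "IGHV1-2", heterozygous=False)
        assert occ2.slots_occupied == 2


class TestBackgroundNull:
    def _cohort(self, db, freqs, neighbor_subjects=()):
        records, occs = {}, {}
        for i, f in enumerate(freqs):
            sid = f"s{i}"
            records[sid] = _rec("IGHV1-2*05", f, sid=sid)
            majors = ["IGHV1-2*02", "IGHV1-2*06"] if sid in neighbor_subjects \
                else ["IGHV1-2*02", "IGHV1-2*04"]
            occs[sid] = OccupancyRecord(sid, "IGHV1-2", 2, majors)
        return records, occs

    def test_all_zero_cohort(self, db):
        records, occs = self._cohort(db, [0, 0, 0, 0])
        bg = background_null("IGHV1-2*05", records, occs, db)
        assert bg.mean_freq == 0.0 and bg.sd_freq == 0.0
        assert not bg.low_confidence

    def test_strata_hand_arithmetic(self, db):
        # 6 subjects: 3 with the 1-nt neighbor in the genotype, 3 without
        freqs = [6e-5, 8e-5, 4e-5, 1e-5, 0.0, 2e-5]
        records, occs = self._cohort(db, freqs,
                                     neighbor_subjects={"s0", "s1", "s2"})
        bg = background_null("IGHV1-2*05", records, occs, db)
        assert bg.nearest_neighbor == "IGHV1-2*06"
        assert isclose(bg.mean_with_neighbor, 6e-5)
        assert isclose(bg.mean_without_neighbor, 1e-5)
        assert isclose(bg.mean_freq, np.mean(freqs))

    def test_carrier_subjects_excluded(self, db):
        records, occs = self._cohort(db, [0, 0, 0])
        # s0's gene slots include the allele itself -> excluded
        occs["s0"] = OccupancyRecord("s0", "IGHV1-2", 2,
                                     ["IGHV1-2*02", "IGHV1-2*05"])
        bg = background_null("IGHV1-2*05", records, occs, db)
        assert "s0" not in bg.cohort_subjects
        assert len(bg.cohort_subjects) == 2 and bg.low_confidence


def _bg(mean, with_n=None, without_n=None, low=False):
    return BackgroundModel("IGHV1-2*05", ["a", "b", "c"], mean, mean / 2,
                           "IGHV1-2*06", with_n, None, without_n, None, low)


def _occ(slots, open_slot=None, majors=()):
    return OccupancyRecord("s", "IGHV1-2", slots, list(majors), open_slot)


class TestDetect:
    def test_clear_carrier(self):
        rec = _rec("IGHV1-2*05", 0.0006, "H2", n_total=200_000)
        call = detect(rec, _occ(1, "H2"), _bg(1e-5, without_n=1e-5), False)
        assert call.status == "CARRIER"
        assert isclose(call.fold_over_background, 60)

    def test_read_floor_beats_fold(self):
        rec = AlleleExpressionRecord("s", "IGHV1-2*05", 2, 200_000)
        call = detect(rec, _occ(2), _bg(1e-9, without_n=1e-9), False)
        assert call.status == "NON_CARRIER"

    def test_small_fold_is_background(self):
        rec = AlleleExpressionRecord("s", "IGHV1-2*05", 24, 2_000_000)
        call = detect(rec, _occ(2), _bg(1e-5, without_n=1e-5), False)
        assert call.status == "NON_CARRIER"  # fold 1.2 < 10

    def test_neighbor_stratum_raises_the_bar(self):
        rec = AlleleExpressionRecord("s", "IGHV1-2*05", 12, 100_000)
        with_n, without_n = 6e-5, 5e-6
        occ = _occ(2, majors=["IGHV1-2*02", "IGHV1-2*06"])
        hi = detect(rec, occ, _bg(3e-5, with_n, without_n), True)
        lo = detect(rec, occ, _bg(3e-5, with_n, without_n), False)
        assert hi.status == "NON_CARRIER"  # 1.2e-4 < 10 * 6e-5
        assert lo.status == "CARRIER"      # 1.2e-4 >= 10 * 5e-6

    def test_open_slot_mismatch_rejects(self):
        rec = _rec("IGHV1-2*05", 0.0006, "H1", n_total=200_000)
        call = detect(rec, _occ(1, "H2"), _bg(1e-5, without_n=1e-5), False)
        assert call.status == "NON_CARRIER"
        assert call.haplotype_consistent is False

    def test_no_anchored_reads_is_ambiguous(self):
        rec = AlleleExpressionRecord("s", "IGHV1-2*05", 120, 200_000,
                                     HaplotypeAssignment("IGHV1-2*05", 0, 0,
                                                         "UNDETERMINED"))
        call = detect(rec, _occ(1, "H2"), _bg(1e-5, without_n=1e-5), False)
        assert call.status == "AMBIGUOUS"

    def test_zero_background_uses_absolute_floor(self):
        bg = _bg(0.0, with_n=0.0, without_n=0.0)
        weak = AlleleExpressionRecord("s", "IGHV1-2*05", 8, 200_000)
        strong = AlleleExpressionRecord("s", "IGHV1-2*05", 12, 200_000)
        assert detect(weak, _occ(2), bg, False).status == "NON_CARRIER"
        assert detect(strong, _occ(2), bg, False).status == "CARRIER"


class TestFoldDifference:
    def test_per_copy_contrast(self):
        # mirrors the reported per-copy contrast magnitudes
        assert isclose(fold_difference([0.00056], [0.0096]), 17.142857,
                       rel_tol=1e-6)

    def test_equal_means_unity(self):
        assert fold_difference([0.01, 0.03], [0.02]) == 1.0

    def test_zero_rare_is_infinite(self):
        assert fold_difference([0.0], [0.01]) == float("inf")


class TestCosegregation:
    def _calls(self, carriers, hap="H1", allele="A"):
        return {s: DetectionCall(s, allele, "CARRIER", 10, 1e-4, 20.0, True,
                                 hap)
                for s in carriers}

    def test_perfect_overlap_closed_form(self):
        a = self._calls({"s1", "s2", "s3", "s4", "s5", "s6"})
        b = self._calls({"s1", "s2", "s3", "s4", "s5", "s6"}, allele="B")
        res = cosegregation(a, b, 35)
        assert res.overlap == 6
        assert isclose(res.p_value, 1 / comb(35, 6), rel_tol=1e-12)
        assert res.colocalized == 6

    def test_haplotype_mismatch_not_colocalized(self):
        a = self._calls({"s1"}, hap="H1")
        b = self._calls({"s1"}, hap="H2", allele="B")
        assert cosegregation(a, b, 10).colocalized == 0

    def test_zero_carriers_degenerate(self):
        res = cosegregation({}, self._calls({"s1"}), 35)
        assert res.degenerate and res.p_value == 1.0


class TestMannWhitney:
    def test_two_vs_two_enumeration(self):
        r = mann_whitney_one_sided([3, 4], [1, 2])
        assert r.method == "exact"
        assert isclose(r.p_value, 1 / 6, rel_tol=1e-12)

    def test_identical_singletons_degenerate(self):
        r = mann_whitney_one_sided([1.0], [1.0])
        assert r.degenerate and r.p_value == 1.0

    def test_ties_fall_back_to_normal_approx(self):
        r = mann_whitney_one_sided([1, 2, 2, 3], [1, 2, 2, 2])
        assert r.method == "normal_approx"
        assert 0 < r.p_value <= 1

    def test_large_samples_agree_with_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 1, 40)
        y = rng.normal(0.0, 1, 35)
        r = mann_whitney_one_sided(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="greater",
                               method="asymptotic").pvalue
        assert isclose(r.p_value, ref, rel_tol=1e-6)


class TestCohortSummary:
    def test_mean_sd_hand_example(self):
        calls = {"IGHV1-2*05": {
            s: DetectionCall(s, "IGHV1-2*05", "CARRIER", 10, f, 20.0, True,
                             "H1")
            for s, f in (("a", 1e-4), ("b", 2e-4), ("c", 3e-4))}}
        records = {s: {"IGHV1-2*05": AlleleExpressionRecord(
            s, "IGHV1-2*05", int(f * 1e6), 1_000_000)}
            for s, f in (("a", 1e-4), ("b", 2e-4), ("c", 3e-4))}
        tab = cohort_summary(calls, records)
        row = tab.iloc[0]
        assert row.carrier_count == 3 and row.haplotype_count == 3
        assert isclose(row.mean_freq_pct, 0.02)
        assert isclose(row.sd_freq_pct, 0.01)


class TestCohortProperties:
    def test_frequency_invariant_to_read_order(self):
        df = _ann(30, 100)
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = expression_frequency(df, "IGHV1-2*05", "s")
        b = expression_frequency(shuffled, "IGHV1-2*05", "s")
        assert (a.n_unique, a.frequency) == (b.n_unique, b.frequency)

    def test_deleted_haplotypes_flagged_as_candidates(self, db):
        """A gene on one haplotype of one subject and absent in another:
        exactly the three empty haplotype slots become deletion candidates."""
        import ighvrare as iv
        from ighvrare.simulate import HaplotypeSpec, SubjectSpec

        def subject(sid, h1_w, h2_w, seed):
            spec = SubjectSpec(
                sid, (HaplotypeSpec("H1", h1_w, "IGHJ6*02"),
                      HaplotypeSpec("H2", h2_w, "IGHJ6*03")),
                n_reads=2000, seed=seed)
            reads, _ = iv.simulate_repertoire(spec, db)
            ann = iv.annotate_sequences([r.read_id for r in reads],
                                        [r.sequence for r in reads], db)
            return iv.SubjectRepertoire.from_annotated(sid, ann)

        common1 = {"IGHV1-2*02": 0.4, "IGHV3-23*01": 0.4}
        common2 = {"IGHV1-2*04": 0.4, "IGHV3-23*01": 0.4}
        subjects = [
            subject("A", {**common1, "IGHV7-4-1*01": 0.2},
                    {**common2, "IGHV4-59*01": 0.2}, seed=21),
            subject("B", {**common1, "IGHV4-59*01": 0.2},
                    {**common2, "IGHV4-59*01": 0.2}, seed=22),
        ]
        res = analyze_cohort(subjects, db)
        dels = res.deletion_candidates
        flagged = dels[dels.gene == "IGHV7-4-1"]
        assert sorted(map(tuple, flagged[["subject_id", "haplotype"]]
                          .to_numpy())) == [("A", "H2"), ("B", "H1"),
                                            ("B", "H2")]
        # fully populated genes yield no candidates
        assert dels[dels.gene == "IGHV1-2"].empty
        assert dels[dels.gene == "IGHV3-23"].empty
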