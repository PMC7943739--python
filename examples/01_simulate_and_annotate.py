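"""Simulate a small 5'RACE-like heavy-chain repertoire and annotate it.

Builds one IGHJ6-heterozygous subject on the bundled synthetic germline
locus, simulates 2,000 reads with ground truth, and runs the annotator:
unique V/J assignment, junction extraction, frame and productivity calls.
"""

import ighvrare as iv
from ighvrare.cohorts import haplotyping_cohort

db = iv.example_locus()
print(f"germline locus: {len(db)} alleles {db.segment_counts()}")

specs, _ = haplotyping_cohort(seed=1, n_subjects=1, n_reads=2000)
reads, log = iv.simulate_repertoire(specs[0], db)
print(f"simulated {len(reads)} reads "
      f"({sum(not r.true_in_frame for r in reads)} out-of-frame passengers)")

ann = iv.annotate_sequences([r.read_id for r in reads],
                            [r.sequence for r in reads], db)
buckets = ann["flag"].replace("", "unique").value_counts().to_dict()
print(f"annotation buckets: {buckets}")
# 'unique' reads are unequivocally assigned to a single V and J allele;
# only those enter allele-frequency numerators downstream.

correct = (ann.loc[ann.flag == "", "v_call"].to_numpy()
           == [r.true_v for r, f in zip(reads, ann.flag) if f == ""]).mean()
print(f"V-call accuracy on uniquely assigned reads: {100 * correct:.1f}%")
print(f"productive fraction: {ann['productive'].mean():.3f}  "
      "(in-frame, stop-free, anchors intact)")
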