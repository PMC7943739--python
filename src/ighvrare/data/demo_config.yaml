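# Demo pipeline configuration: a small carrier-recovery cohort.
# Two of six subjects carry the poorly expressed allele IGHV1-2*05 at
# ~0.05% of reads on one haplotype; the rest are non-carriers whose both
# IGHV1-2 slots hold major alleles.
seed: 7
germline: bundled
cohort:
  kind: detection
  n_subjects: 6
  n_carriers: 2
  n_reads: 20000
  shm_rate: 0.02
  seq_error_rate: 0.001
target_alleles: [IGHV1-2*05]
thresholds: {}
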