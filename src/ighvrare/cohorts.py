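"""Study-condition cohort builders on the synthetic locus.

These functions fix the simulation conditions under which the package's
recovery properties are demonstrated; the numbers here (sample sizes,
expression weights, noise rates) are the study conditions themselves, not
tuning knobs.  All subjects are IGHJ6-heterozygous (IGHJ6*02 on haplotype
1, IGHJ6*03 on haplotype 2) so every cohort is haplotypable.

Expression weights are relative transcript weights within a haplotype; a
read draws its haplotype uniformly, so an allele with normalized weight w
on one haplotype contributes ~w/2 of all reads.
"""

from __future__ import annotations

from .simulate import HaplotypeSpec, SubjectSpec

__all__ = [
    "RARE_ALLELE",
    "NEIGHBOR_ALLELE",
    "detection_cohort",
    "haplotyping_cohort",
    "neighbor_background_pair",
    "focal_codon_subject",
    "DETECTION_N_SUBJECTS",
    "DETECTION_N_CARRIERS",
]

RARE_ALLELE = "IGHV1-2*05"
NEIGHBOR_ALLELE = "IGHV1-2*06"  # 1 nt from the rare allele

DETECTION_N_SUBJECTS = 24
DETECTION_N_CARRIERS = 8
DETECTION_N_NEIGHBOR_NONCARRIERS = 6

# Shared major-allele backbone (relative weights within a haplotype).
_H1_COMMON = {"IGHV3-23*01": 0.33, "IGHV1-3*01": 0.25, "IGHV4-59*01": 0.20,
              "IGHV4-4*07": 0.19}
_H2_COMMON = {"IGHV3-23*01": 0.30, "IGHV1-3*01": 0.25, "IGHV4-59*01": 0.15,
              "IGHV4-4*02": 0.15, "IGHV1-2*02": 0.15}

# Rare-allele weight: ~0.0011 of haplotype-1 reads -> ~0.055% of all reads,
# the poorly-expressed band (a few hundredths of a percent up to ~0.1%).
_RARE_WEIGHT = 0.0011
# Neighbor weight in neighbor-carrying non-carriers: ~0.6% of all reads,
# enough to source measurable 1-nt misassignment background.
_NEIGHBOR_WEIGHT = 0.012


def _hap(hid: str, j6: str, weights: dict[str, float],
         j_other_usage: float = 0.3) -> HaplotypeSpec:
    return HaplotypeSpec(haplotype_id=hid, v_expression=dict(weights),
                         j6_allele=j6, j_other_usage=j_other_usage)


def detection_cohort(
    seed: int,
    n_subjects: int = DETECTION_N_SUBJECTS,
    n_carriers: int = DETECTION_N_CARRIERS,
    n_reads: int = 20_000,
    shm_rate: float = 0.02,
    seq_error_rate: float = 0.001,
) -> tuple[list[SubjectSpec], dict[str, bool]]:
    """Carrier-recovery cohort: ``n_carriers`` subjects express the rare
    allele at ~0.05% of reads on haplotype 1; the rest are non-carriers
    with both IGHV1-2 slots occupied by major alleles.  About 3/8 of the
    non-carriers (6 of 16 at the default size) carry the rare allele's
    1-nt neighbor, the misassignment background source; the rest carry
    only distant alleles.  Returns the specs and the ground-truth carrier
    map.
    """
    n_non = n_subjects - n_carriers
    n_neighbor = min(DETECTION_N_NEIGHBOR_NONCARRIERS,
                     max(1, round(0.375 * n_non)))
    specs: list[SubjectSpec] = []
    truth: dict[str, bool] = {}
    for i in range(n_subjects):
        sid = f"S{i:02d}"
        is_carrier = i < n_carriers
        has_neighbor = (not is_carrier and i < n_carriers + n_neighbor)
        h1 = dict(_H1_COMMON)
        if is_carrier:
            h1[RARE_ALLELE] = _RARE_WEIGHT
        elif has_neighbor:
            h1[NEIGHBOR_ALLELE] = _NEIGHBOR_WEIGHT
        else:
            h1["IGHV1-2*04"] = 0.02
        if i % 4 == 0:
            h1["IGHV7-4-1*02"] = 0.01
        specs.append(SubjectSpec(
            subject_id=sid,
            haplotypes=(_hap("H1", "IGHJ6*02", h1),
                        _hap("H2", "IGHJ6*03", _H2_COMMON)),
            n_reads=n_reads,
            shm_rate=shm_rate,
            seq_error_rate=seq_error_rate,
            trim_mean=2.0,
            n_insert_max=8,
            passenger_fraction=0.15,
            seed=seed * 1009 + i,
        ))
        truth[sid] = is_carrier
    return specs, truth


def haplotyping_cohort(
    seed: int,
    n_subjects: int = 3,
    n_reads: int = 4_000,
) -> tuple[list[SubjectSpec], dict[str, dict[str, str]]]:
    """Noise-free cohort for haplotype recovery: several genes with two
    alleles placed on opposite chromosomes, plus single-haplotype alleles.
    Returns specs and the true haplotype of every expressed allele.
    """
    h1_w = {"IGHV1-2*02": 0.30, "IGHV1-3*01": 0.25, "IGHV4-4*02": 0.20,
            "IGHV3-23*01": 0.15, "IGHV7-4-1*01": 0.10}
    h2_w = {"IGHV1-2*04": 0.30, "IGHV1-3*02": 0.25, "IGHV4-4*07": 0.20,
            "IGHV3-23*01": 0.15, "IGHV4-59*01": 0.10}
    specs, truth = [], {}
    for i in range(n_subjects):
        sid = f"HS{i:02d}"
        specs.append(SubjectSpec(
            subject_id=sid,
            haplotypes=(_hap("H1", "IGHJ6*02", h1_w),
                        _hap("H2", "IGHJ6*03", h2_w)),
            n_reads=n_reads,
            shm_rate=0.0, seq_error_rate=0.0,
            trim_mean=1.0, n_insert_max=6,
            passenger_fraction=0.1,
            seed=seed * 2003 + i,
        ))
        truth[sid] = {
            **{a: "H1" for a in h1_w if a != "IGHV3-23*01"},
            **{a: "H2" for a in h2_w if a != "IGHV3-23*01"},
            "IGHV3-23*01": "BOTH",
        }
    return specs, truth


def neighbor_background_pair(
    seed: int,
    n_reads: int = 20_000,
    shm_rate: float = 0.02,
) -> tuple[SubjectSpec, SubjectSpec]:
    """Two non-carrier genotypes for the neighbor-background contrast: one
    expresses the rare allele's 1-nt neighbor, the other only alleles >=5
    nt away from it.  Neither carries the rare allele; any reads assigned
    to it are misassignment background.
    """
    near_h1 = dict(_H1_COMMON)
    near_h1[NEIGHBOR_ALLELE] = 0.04  # ~2% of reads, like a common allele
    far_h1 = dict(_H1_COMMON)
    far_h1["IGHV1-2*04"] = 0.04
    common = dict(n_reads=n_reads, shm_rate=shm_rate, seq_error_rate=0.001,
                  trim_mean=2.0, n_insert_max=8, passenger_fraction=0.15)
    near = SubjectSpec(
        subject_id="NEAR",
        haplotypes=(_hap("H1", "IGHJ6*02", near_h1),
                    _hap("H2", "IGHJ6*03", _H2_COMMON)),
        seed=seed * 4001, **common)
    far = SubjectSpec(
        subject_id="FAR",
        haplotypes=(_hap("H1", "IGHJ6*02", far_h1),
                    _hap("H2", "IGHJ6*03", _H2_COMMON)),
        seed=seed * 4001 + 1, **common)
    return near, far


def focal_codon_subject(
    seed: int,
    n_reads: int = 3_000,
    shm_rate: float = 0.05,
) -> SubjectSpec:
    """A class-switched-like subject expressing IGHV7-4-1*01 (the allele
    with the unusual cysteine at IMGT codon 92) at high frequency under
    strong hypermutation, for focal-codon substitution analysis."""
    h1 = {"IGHV7-4-1*01": 0.5, "IGHV3-23*01": 0.5}
    h2 = {"IGHV1-2*02": 0.5, "IGHV1-3*01": 0.5}
    return SubjectSpec(
        subject_id="FOCAL",
        haplotypes=(_hap("H1", "IGHJ6*02", h1),
                    _hap("H2", "IGHJ6*03", h2)),
        n_reads=n_reads,
        shm_rate=shm_rate, seq_error_rate=0.0,
        trim_mean=2.0, n_insert_max=8,
        passenger_fraction=0.1,
        seed=seed * 5003,
    )
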