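"""Rare-allele expression accounting, background nulls and carrier calling.

The analysis core.  Poorly expressed germline alleles fall below the
filtering thresholds of genotype-inference tools, but their reads are still
present in the repertoire at frequencies far above the misassignment
background observed in subjects whose both haplotype slots of the gene are
occupied by other alleles.  A subject is called a CARRIER of an allele when

  (i)   enough reads are uniquely assigned to it (absolute read floor),
  (ii)  its read frequency exceeds ``fold_min`` times the background null
        estimated from non-carrier genotypes — stratified by whether the
        allele's nearest germline neighbor is in the subject's genotype,
        because misassignment from a 1-nt neighbor inflates the background
        roughly tenfold, and
  (iii) when the subject has exactly one open haplotype slot for the gene
        and IGHJ6-anchored reads exist, those reads sit dominantly on the
        open slot.

Frequencies are reads uniquely assigned to the allele divided by the total
number of reads in the subject's input file (ambiguous and flagged reads
stay in the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .germline import GermlineDatabase, nearest_neighbor
from .haplotype import (
    HaplotypeAssignment,
    HaplotypeContext,
    assign_haplotype,
    detect_j6_heterozygosity,
)
from .stats import hypergeom_tail_p

__all__ = [
    "DetectionConfig",
    "AlleleExpressionRecord",
    "OccupancyRecord",
    "BackgroundModel",
    "DetectionCall",
    "SubjectRepertoire",
    "CohortResult",
    "expression_frequency",
    "occupancy",
    "background_null",
    "detect",
    "fold_difference",
    "cosegregation",
    "cohort_summary",
    "analyze_cohort",
]


@dataclass
class DetectionConfig:
    """All thresholds of the analysis, with their defaults.

    ``major_threshold`` (0.2% of reads) separates major alleles — the ones
    genotype inference sees — from the rare band; ``fold_min`` and
    ``read_min`` are the carrier-evidence margins; the rest parameterize
    haplotyping and annotation.
    """

    major_threshold: float = 0.002
    fold_min: float = 10.0
    read_min: int = 5
    dominance_frac: float = 0.85
    min_anchored_reads: int = 5
    min_allele_frac: float = 0.2
    min_j6_reads: int = 50
    max_mismatch_frac: float = 0.10


@dataclass
class AlleleExpressionRecord:
    subject_id: str
    allele: str
    n_unique: int
    n_total: int
    haplotype: HaplotypeAssignment | None = None

    @property
    def frequency(self) -> float:
        return self.n_unique / self.n_total

    @property
    def frequency_pct(self) -> float:
        return 100.0 * self.frequency


@dataclass
class OccupancyRecord:
    subject_id: str
    gene: str
    slots_occupied: int | None  # 0/1/2, None = unknown (no haplotype context)
    major_alleles: list[str] = field(default_factory=list)
    open_slot_haplotype: str | None = None  # H1/H2 when slots_occupied == 1


@dataclass
class BackgroundModel:
    allele: str
    cohort_subjects: list[str]
    mean_freq: float
    sd_freq: float
    nearest_neighbor: str | None = None
    mean_with_neighbor: float | None = None
    sd_with_neighbor: float | None = None
    mean_without_neighbor: float | None = None
    sd_without_neighbor: float | None = None
    low_confidence: bool = False


@dataclass
class DetectionCall:
    subject_id: str
    allele: str
    status: str  # CARRIER | NON_CARRIER | AMBIGUOUS
    n_unique: int
    frequency: float
    fold_over_background: float
    haplotype_consistent: bool | None
    dominant_haplotype: str | None = None
    notes: str = ""


@dataclass
class SubjectRepertoire:
    """One subject's annotated repertoire plus haplotype context."""

    subject_id: str
    annotated: pd.DataFrame
    context: HaplotypeContext
    n_total: int

    @classmethod
    def from_annotated(
        cls, subject_id: str, annotated: pd.DataFrame,
        config: DetectionConfig | None = None,
    ) -> "SubjectRepertoire":
        config = config or DetectionConfig()
        ctx = detect_j6_heterozygosity(
            annotated, subject_id,
            min_allele_frac=config.min_allele_frac,
            min_reads=config.min_j6_reads)
        return cls(subject_id, annotated, ctx, n_total=len(annotated))


def expression_frequency(
    annotated: pd.DataFrame,
    allele: str,
    subject_id: str = "",
    n_total: int | None = None,
    context: HaplotypeContext | None = None,
    dominance_frac: float = 0.85,
    min_anchored_reads: int = 5,
) -> AlleleExpressionRecord:
    """Per-allele expression record: reads uniquely assigned to the allele
    over the total rows of the subject's input file."""
    n_total = len(annotated) if n_total is None else n_total
    if n_total == 0:
        raise ValueError("n_total must be positive")
    n_unique = int((annotated["v_unique"]
                    & (annotated["v_call"] == allele)).sum())
    hap = None
    if context is not None and context.heterozygous:
        hap = assign_haplotype(allele, context, annotated,
                               dominance_frac, min_anchored_reads)
    return AlleleExpressionRecord(subject_id, allele, n_unique, n_total, hap)


_ANCHOR_SETS = {"H1": {"H1"}, "H2": {"H2"}, "BOTH": {"H1", "H2"},
                "UNDETERMINED": set()}


def occupancy(
    records: list[AlleleExpressionRecord],
    gene: str,
    major_threshold: float = 0.002,
    heterozygous: bool = True,
) -> OccupancyRecord:
    """How many haplotype slots of ``gene`` are held by major alleles.

    A single major allele haplotyped to BOTH anchors is the homozygous case
    and occupies both slots.  Without a heterozygous IGHJ6 context slots can
    be established (as 2) only when two distinct major alleles exist;
    otherwise occupancy is unknown.
    """
    majors = [r for r in records
              if r.allele.split("*")[0] == gene
              and r.frequency >= major_threshold]
    subject_id = records[0].subject_id if records else ""
    names = sorted(r.allele for r in majors)
    if not heterozygous:
        slots = 2 if len(names) >= 2 else None
        return OccupancyRecord(subject_id, gene, slots, names, None)
    used: set[str] = set()
    for r in majors:
        if r.haplotype is not None:
            used |= _ANCHOR_SETS[r.haplotype.call]
    slots = len(used)
    open_slot = None
    if slots == 1:
        open_slot = ({"H1", "H2"} - used).pop()
    return OccupancyRecord(subject_id, gene, slots, names, open_slot)


def _mean_sd(freqs: list[float]) -> tuple[float, float]:
    arr = np.asarray(freqs, dtype=float)
    if len(arr) == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def background_null(
    allele: str,
    records: dict[str, AlleleExpressionRecord],
    occupancies: dict[str, OccupancyRecord],
    db: GermlineDatabase,
) -> BackgroundModel:
    """Null read-frequency model for ``allele`` from non-carrier genotypes.

    The cohort is every subject whose both haplotype slots of the allele's
    gene are occupied by *other* major alleles — reads of ``allele`` seen
    there are misassignment background.  The cohort is additionally
    stratified by whether the allele's nearest germline neighbor is among
    the subject's major alleles, since a near-identical expressed neighbor
    inflates the background.
    """
    neighbor, _ = nearest_neighbor(db[allele], db)
    cohort, with_n, without_n = [], [], []
    for sid, rec in records.items():
        occ = occupancies.get(sid)
        if occ is None or occ.slots_occupied != 2:
            continue
        if allele in occ.major_alleles:
            continue
        cohort.append(sid)
        majors_all = occ.major_alleles
        (with_n if neighbor in majors_all else without_n).append(rec.frequency)
    mean, sd = _mean_sd([records[s].frequency for s in cohort])
    mw, sdw = _mean_sd(with_n) if with_n else (None, None)
    mo, sdo = _mean_sd(without_n) if without_n else (None, None)
    return BackgroundModel(
        allele=allele, cohort_subjects=cohort,
        mean_freq=mean if cohort else float("nan"),
        sd_freq=sd if cohort else float("nan"),
        nearest_neighbor=neighbor,
        mean_with_neighbor=mw, sd_with_neighbor=sdw,
        mean_without_neighbor=mo, sd_without_neighbor=sdo,
        low_confidence=len(cohort) < 3,
    )


def _dominant_haplotype(hap: HaplotypeAssignment | None,
                        dominance_frac: float) -> str | None:
    if hap is None or hap.n_h1 + hap.n_h2 == 0:
        return None
    frac = hap.fraction_h1
    if frac >= dominance_frac:
        return "H1"
    if 1 - frac >= dominance_frac:
        return "H2"
    return "BOTH"


def detect(
    record: AlleleExpressionRecord,
    occ: OccupancyRecord,
    background: BackgroundModel,
    subject_has_neighbor: bool,
    fold_min: float = 10.0,
    read_min: int = 5,
    dominance_frac: float = 0.85,
) -> DetectionCall:
    """Carrier call for one subject and one allele.

    The background mean compared against is the stratum matching the
    subject's own genotype (nearest neighbor present / absent); when that
    stratum is empty or zero the pooled mean is used, and when every mean
    is zero (or the background is low-confidence) an absolute floor of 10
    reads in the subject's file applies instead.
    """
    freq = record.frequency
    notes = []

    mean = None
    if not background.low_confidence:
        strat = (background.mean_with_neighbor if subject_has_neighbor
                 else background.mean_without_neighbor)
        if strat is not None and strat > 0:
            mean = strat
        elif background.mean_freq and background.mean_freq > 0 \
                and np.isfinite(background.mean_freq):
            mean = background.mean_freq
            notes.append("pooled_background")
    else:
        notes.append("low_confidence_background")

    if mean is not None:
        fold = freq / mean
        pass_fold = freq >= fold_min * mean
    else:
        fold = float("inf") if freq > 0 else 0.0
        pass_fold = freq >= 10.0 / record.n_total
        notes.append("absolute_floor")

    pass_reads = record.n_unique >= read_min

    # (iii) haplotype consistency with the open slot
    consistent: bool | None
    dom = _dominant_haplotype(record.haplotype, dominance_frac)
    if occ.slots_occupied == 1 and occ.open_slot_haplotype in ("H1", "H2"):
        if dom is None:
            consistent = None
            notes.append("no_anchored_reads")
        else:
            consistent = dom == occ.open_slot_haplotype
    elif occ.slots_occupied in (0, 2):
        # no open-slot constraint: zero slots leaves both anchors open,
        # two slots leaves none
        consistent = True
    else:
        consistent = None
        notes.append("occupancy_unknown")

    if not (pass_reads and pass_fold):
        status = "NON_CARRIER"
    elif consistent is True:
        status = "CARRIER"
    elif consistent is None:
        status = "AMBIGUOUS"
    else:
        status = "NON_CARRIER"
        notes.append("haplotype_inconsistent")

    return DetectionCall(
        subject_id=record.subject_id, allele=record.allele, status=status,
        n_unique=record.n_unique, frequency=freq,
        fold_over_background=fold, haplotype_consistent=consistent,
        dominant_haplotype=dom, notes=";".join(notes),
    )


def fold_difference(
    rare_frequencies: list[float],
    major_per_copy_frequencies: list[float],
) -> float:
    """How many fold lower the rare allele is expressed than a single copy
    of a major allele: mean major per-copy frequency / mean rare frequency.
    """
    if not rare_frequencies or not major_per_copy_frequencies:
        raise ValueError("both groups must be non-empty")
    rare = float(np.mean(rare_frequencies))
    major = float(np.mean(major_per_copy_frequencies))
    if rare == 0:
        return float("inf")
    return major / rare


@dataclass
class CosegregationResult:
    n_a: int
    n_b: int
    overlap: int
    cohort_size: int
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    colocalized: int
    degenerate: bool = False


def cosegregation(
    calls_a: dict[str, DetectionCall],
    calls_b: dict[str, DetectionCall],
    cohort_size: int,
) -> CosegregationResult:
    """Carrier co-occurrence of two alleles over one cohort.

    2x2 carrier table, one-sided hypergeometric tail p, and the number of
    shared carriers in which both alleles' dominant haplotype anchors agree
    (co-localization on the same chromosome).
    """
    a_set = {s for s, c in calls_a.items() if c.status == "CARRIER"}
    b_set = {s for s, c in calls_b.items() if c.status == "CARRIER"}
    overlap = a_set & b_set
    n_a, n_b, k = len(a_set), len(b_set), len(overlap)
    table = ((k, n_a - k),
             (n_b - k, cohort_size - n_a - n_b + k))
    degenerate = n_a == 0 or n_b == 0
    p = 1.0 if degenerate else hypergeom_tail_p(k, n_a, n_b, cohort_size)
    coloc = sum(
        1 for s in overlap
        if calls_a[s].dominant_haplotype is not None
        and calls_a[s].dominant_haplotype == calls_b[s].dominant_haplotype
    )
    return CosegregationResult(n_a, n_b, k, cohort_size, table, p, coloc,
                               degenerate)


@dataclass
class CohortResult:
    detection: pd.DataFrame
    calls: dict[str, dict[str, DetectionCall]]  # allele -> subject -> call
    backgrounds: dict[str, BackgroundModel]
    occupancies: dict[str, dict[str, OccupancyRecord]]  # subject -> gene -> occ
    records: dict[str, dict[str, AlleleExpressionRecord]]  # subject -> allele
    summary: pd.DataFrame
    deletion_candidates: pd.DataFrame


def analyze_cohort(
    subjects: list[SubjectRepertoire],
    db: GermlineDatabase,
    target_alleles: list[str] | None = None,
    config: DetectionConfig | None = None,
) -> CohortResult:
    """Run expression accounting, occupancy, background nulls and carrier
    calls for a cohort of annotated subjects.

    ``target_alleles`` defaults to every V allele in the database; an
    allele that is itself major in a subject is recorded as a CARRIER with
    note "major_allele" (inference tools see those; the detector's work is
    the rare band).
    """
    config = config or DetectionConfig()
    v_alleles = sorted(a.name for a in db.by_segment("V"))
    targets = target_alleles if target_alleles is not None else v_alleles
    genes = sorted({a.split("*")[0] for a in v_alleles})

    records: dict[str, dict[str, AlleleExpressionRecord]] = {}
    occs: dict[str, dict[str, OccupancyRecord]] = {}
    for subj in subjects:
        recs = {
            allele: expression_frequency(
                subj.annotated, allele, subj.subject_id, subj.n_total,
                subj.context, config.dominance_frac,
                config.min_anchored_reads)
            for allele in v_alleles
        }
        records[subj.subject_id] = recs
        occs[subj.subject_id] = {
            gene: occupancy([recs[a] for a in v_alleles
                             if a.split("*")[0] == gene],
                            gene, config.major_threshold,
                            subj.context.heterozygous)
            for gene in genes
        }

    backgrounds: dict[str, BackgroundModel] = {}
    calls: dict[str, dict[str, DetectionCall]] = {}
    rows = []
    for allele in targets:
        gene = allele.split("*")[0]
        allele_recs = {sid: records[sid][allele] for sid in records}
        gene_occs = {sid: occs[sid][gene] for sid in occs}
        bg = background_null(allele, allele_recs, gene_occs, db)
        backgrounds[allele] = bg
        calls[allele] = {}
        for subj in subjects:
            rec = allele_recs[subj.subject_id]
            occ = gene_occs[subj.subject_id]
            if allele in occ.major_alleles:
                call = DetectionCall(
                    subj.subject_id, allele, "CARRIER", rec.n_unique,
                    rec.frequency, float("inf"), True,
                    _dominant_haplotype(rec.haplotype, config.dominance_frac),
                    notes="major_allele")
            else:
                has_nb = bg.nearest_neighbor in occ.major_alleles
                call = detect(rec, occ, bg, has_nb, config.fold_min,
                              config.read_min, config.dominance_frac)
            calls[allele][subj.subject_id] = call
            rows.append({
                "subject_id": call.subject_id, "allele": allele,
                "gene": gene, "status": call.status,
                "n_unique": call.n_unique,
                "frequency_pct": 100 * call.frequency,
                "fold_over_background": call.fold_over_background,
                "dominant_haplotype": call.dominant_haplotype or "",
                "haplotype_consistent": call.haplotype_consistent,
                "notes": call.notes,
            })
    detection = pd.DataFrame(rows).sort_values(
        ["gene", "allele", "subject_id"]).reset_index(drop=True)

    summary = cohort_summary(calls, records)
    deletions = _deletion_candidates(subjects, calls, occs, genes)
    return CohortResult(detection, calls, backgrounds, occs, records,
                        summary, deletions)


def cohort_summary(
    calls: dict[str, dict[str, DetectionCall]],
    records: dict[str, dict[str, AlleleExpressionRecord]],
) -> pd.DataFrame:
    """Deterministic per-allele cohort table: carrier and haplotype counts
    and mean +/- SD carrier frequency (percent, 4 significant digits)."""
    rows = []
    for allele in sorted(calls):
        subj_calls = calls[allele]
        carriers = [s for s, c in subj_calls.items() if c.status == "CARRIER"]
        hap_count = 0
        for s in carriers:
            dom = subj_calls[s].dominant_haplotype
            hap_count += 2 if dom == "BOTH" else 1
        freqs = [100 * records[s][allele].frequency for s in carriers]
        mean, sd = _mean_sd(freqs) if freqs else (float("nan"), float("nan"))
        rows.append({
            "gene": allele.split("*")[0],
            "allele": allele,
            "carrier_count": len(carriers),
            "haplotype_count": hap_count,
            "mean_freq_pct": float(f"{mean:.4g}") if freqs else float("nan"),
            "sd_freq_pct": float(f"{sd:.4g}") if freqs else float("nan"),
        })
    return (pd.DataFrame(rows)
            .sort_values(["gene", "allele"]).reset_index(drop=True))


def _deletion_candidates(
    subjects: list[SubjectRepertoire],
    calls: dict[str, dict[str, DetectionCall]],
    occs: dict[str, dict[str, OccupancyRecord]],
    genes: list[str],
) -> pd.DataFrame:
    """Anchored haplotypes with no detected allele of a gene — reported as
    deletion CANDIDATES only, never deletion assertions."""
    rows = []
    for subj in subjects:
        if not subj.context.heterozygous:
            continue
        for gene in genes:
            used: set[str] = set()
            for allele, subj_calls in calls.items():
                if allele.split("*")[0] != gene:
                    continue
                call = subj_calls.get(subj.subject_id)
                if call is None or call.status != "CARRIER":
                    continue
                dom = call.dominant_haplotype
                if dom in ("H1", "H2"):
                    used.add(dom)
                elif dom == "BOTH":
                    used |= {"H1", "H2"}
            for hap in ("H1", "H2"):
                if hap not in used:
                    rows.append({"subject_id": subj.subject_id,
                                 "gene": gene, "haplotype": hap})
    return pd.DataFrame(rows, columns=["subject_id", "gene", "haplotype"])
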