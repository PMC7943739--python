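"""IGHJ6-anchored haplotyping.

A V allele rearranges only to J genes on its own chromosome, so in subjects
heterozygous at IGHJ6 — a J gene used at high frequency — the IGHJ6 allele
observed in a read anchors its V allele to one of the two chromosomes.
Haplotype 1 is, by convention, the haplotype carrying the IGHJ6 allele with
the lowest alphanumeric name, so haplotype labels are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "HaplotypeContext",
    "HaplotypeAssignment",
    "detect_j6_heterozygosity",
    "assign_haplotype",
    "haplotype_table",
]

DEFAULT_MIN_ALLELE_FRAC = 0.2
DEFAULT_MIN_J6_READS = 50
DEFAULT_DOMINANCE_FRAC = 0.85
DEFAULT_MIN_ANCHORED_READS = 5


@dataclass
class HaplotypeContext:
    subject_id: str
    j6_counts: dict[str, int] = field(default_factory=dict)
    heterozygous: bool = False
    h1_allele: str | None = None
    h2_allele: str | None = None


@dataclass
class HaplotypeAssignment:
    v_allele: str
    n_h1: int
    n_h2: int
    call: str  # H1 | H2 | BOTH | UNDETERMINED

    @property
    def fraction_h1(self) -> float | None:
        total = self.n_h1 + self.n_h2
        return self.n_h1 / total if total else None


def detect_j6_heterozygosity(
    annotated: pd.DataFrame,
    subject_id: str = "",
    min_allele_frac: float = DEFAULT_MIN_ALLELE_FRAC,
    min_reads: int = DEFAULT_MIN_J6_READS,
) -> HaplotypeContext:
    """Decide IGHJ6 heterozygosity from uniquely J-assigned reads.

    Heterozygous iff exactly two IGHJ6 alleles each hold at least
    ``min_allele_frac`` of the IGHJ6 reads and at least ``min_reads`` reads;
    a handful of reads on a second allele is annotation noise, and three or
    more substantial alleles make the subject unhaplotypable.
    """
    if annotated.empty:
        return HaplotypeContext(subject_id=subject_id)
    j6 = annotated[annotated["j_unique"]
                   & annotated["j_call"].str.startswith("IGHJ6")]
    counts = j6["j_call"].value_counts().to_dict()
    total = sum(counts.values())
    ctx = HaplotypeContext(subject_id=subject_id, j6_counts=counts)
    if total == 0:
        return ctx
    passing = sorted(
        a for a, n in counts.items()
        if n >= min_reads and n / total >= min_allele_frac
    )
    if len(passing) == 2:
        ctx.heterozygous = True
        ctx.h1_allele, ctx.h2_allele = passing  # lowest alphanumeric = H1
    return ctx


def assign_haplotype(
    v_allele: str,
    context: HaplotypeContext,
    annotated: pd.DataFrame,
    dominance_frac: float = DEFAULT_DOMINANCE_FRAC,
    min_anchored_reads: int = DEFAULT_MIN_ANCHORED_READS,
) -> HaplotypeAssignment:
    """Haplotype call for one V allele from its IGHJ6-anchored reads.

    Uses reads uniquely assigned both to ``v_allele`` and to one of the two
    heterozygous IGHJ6 alleles.  Degenerate inputs (not heterozygous, too
    few anchored reads, no clear dominance) yield UNDETERMINED.
    """
    if not context.heterozygous or annotated.empty:
        return HaplotypeAssignment(v_allele, 0, 0, "UNDETERMINED")
    sub = annotated[annotated["v_unique"] & (annotated["v_call"] == v_allele)
                    & annotated["j_unique"]]
    n_h1 = int((sub["j_call"] == context.h1_allele).sum())
    n_h2 = int((sub["j_call"] == context.h2_allele).sum())
    total = n_h1 + n_h2
    if total < min_anchored_reads:
        return HaplotypeAssignment(v_allele, n_h1, n_h2, "UNDETERMINED")
    frac_h1 = n_h1 / total
    if frac_h1 >= dominance_frac:
        call = "H1"
    elif 1 - frac_h1 >= dominance_frac:
        call = "H2"
    elif min(frac_h1, 1 - frac_h1) >= 1 - dominance_frac:
        call = "BOTH"
    else:
        call = "UNDETERMINED"
    return HaplotypeAssignment(v_allele, n_h1, n_h2, call)


def haplotype_table(
    annotated: pd.DataFrame,
    context: HaplotypeContext,
    dominance_frac: float = DEFAULT_DOMINANCE_FRAC,
    min_anchored_reads: int = DEFAULT_MIN_ANCHORED_READS,
) -> pd.DataFrame:
    """Per-V-allele haplotype table (v_allele, n_h1, n_h2, call) for every
    uniquely assigned V allele seen in the subject."""
    alleles = sorted(
        annotated.loc[annotated["v_unique"], "v_call"].unique())
    rows = []
    for allele in alleles:
        a = assign_haplotype(allele, context, annotated,
                             dominance_frac, min_anchored_reads)
        rows.append({"v_allele": allele, "n_h1": a.n_h1, "n_h2": a.n_h2,
                     "call": a.call})
    return pd.DataFrame(rows, columns=["v_allele", "n_h1", "n_h2", "call"])
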