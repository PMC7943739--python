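"""Functionality profiles and focal-codon substitution tracking.

CDR3-length histograms and productive fractions characterize whether an
allele's rearrangements can encode protein (an out-of-frame-heavy profile
marks passenger rearrangements); the focal-codon profile follows what
somatic hypermutation does to an unusual germline residue (e.g. the
surface cysteine at IMGT position 92 of IGHV7-4-1*01) in productive,
mutated reads, together with whether the germline codon sits in an
RGYW/WRCY or WA/TA hypermutation hotspot context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineDatabase

__all__ = [
    "Cdr3Profile",
    "CodonSubstitutionProfile",
    "cdr3_profile",
    "hotspot_scan",
    "hotspot_context",
    "focal_codon_profile",
    "imgt_codon_to_ungapped_offset",
]

_IUPAC = {"R": "AG", "Y": "CT", "W": "AT", "A": "A", "C": "C", "G": "G",
          "T": "T"}
HOTSPOT_MOTIFS = ("RGYW", "WRCY", "WA", "TA")


@dataclass
class Cdr3Profile:
    allele: str
    histogram: dict[int, int]
    frac_in_frame: float
    frac_productive: float
    n_reads: int

    @property
    def empty(self) -> bool:
        return self.n_reads == 0


@dataclass
class CodonSubstitutionProfile:
    allele: str
    imgt_codon: int
    germline_residue: str
    residue_counts: dict[str, int] = field(default_factory=dict)
    hotspot_context: bool = False
    n_skipped_no_coverage: int = 0

    @property
    def total(self) -> int:
        return sum(self.residue_counts.values())

    @property
    def frac_substituted(self) -> float:
        if self.total == 0:
            return float("nan")
        return 1.0 - self.residue_counts.get(self.germline_residue, 0) / self.total


def cdr3_profile(annotated: pd.DataFrame, allele: str) -> Cdr3Profile:
    """CDR3-length histogram and in-frame/productive fractions over reads
    uniquely assigned to ``allele`` with an extracted junction."""
    sub = annotated[annotated["v_unique"]
                    & (annotated["v_call"] == allele)
                    & (annotated["junction_length"] >= 0)]
    lengths = sub["cdr3_length"].astype(int)
    hist = lengths.value_counts().sort_index().to_dict()
    n = len(sub)
    if n == 0:
        return Cdr3Profile(allele, {}, float("nan"), float("nan"), 0)
    frac_if = float((lengths % 3 == 0).mean())
    frac_prod = float(sub["productive"].mean())
    return Cdr3Profile(allele, {int(k): int(v) for k, v in hist.items()},
                       frac_if, frac_prod, n)


def _matches(seq: str, motif: str) -> bool:
    return len(seq) == len(motif) and all(
        b in _IUPAC[m] for b, m in zip(seq, motif))


def hotspot_scan(sequence: str, position: int) -> dict[str, bool]:
    """Does any RGYW/WRCY 4-mer or WA/TA 2-mer window cover ``position``?

    RGYW and WA are hotspots of the mutator on the top strand; WRCY and TA
    are their reverse-complement partners, so scanning a sequence and its
    reverse complement yields mirrored flags.
    """
    if not 0 <= position < len(sequence):
        raise ValueError(f"position {position} outside sequence of length "
                         f"{len(sequence)}")
    flags = {}
    for motif in HOTSPOT_MOTIFS:
        w = len(motif)
        hit = False
        for start in range(max(0, position - w + 1),
                           min(len(sequence) - w, position) + 1):
            if _matches(sequence[start:start + w], motif):
                hit = True
                break
        flags[motif] = hit
    flags["any"] = any(flags[m] for m in HOTSPOT_MOTIFS)
    return flags


def hotspot_context(sequence: str, start: int, length: int = 3) -> bool:
    """True if any hotspot window overlaps [start, start+length)."""
    return any(hotspot_scan(sequence, p)["any"]
               for p in range(start, start + length))


def imgt_codon_to_ungapped_offset(db_allele, imgt_codon: int) -> int:
    """0-based ungapped offset of the first base of a 1-based IMGT codon.

    Goes through the gapped germline alignment when available (gap columns
    do not exist in the read), else assumes the ungapped sequence starts at
    IMGT position 1 with no gaps before the codon.  Identical for
    indel-free data when no IMGT gap precedes the codon.
    """
    gapped_off = (imgt_codon - 1) * 3
    if db_allele.sequence_gapped is not None:
        prefix = db_allele.sequence_gapped[:gapped_off]
        if db_allele.sequence_gapped[gapped_off] == ".":
            raise ValueError(
                f"IMGT codon {imgt_codon} is a gap column in {db_allele.name}")
        return gapped_off - prefix.count(".")
    return gapped_off


def focal_codon_profile(
    annotated: pd.DataFrame,
    allele: str,
    imgt_codon: int,
    db: GermlineDatabase,
    min_mutations: int = 1,
) -> CodonSubstitutionProfile:
    """Residue spectrum at one IMGT codon over productive, mutated reads
    uniquely assigned to ``allele``.

    A read counts as mutated when it carries at least ``min_mutations``
    V-region mismatches versus germline (use 2 when sequencing error is
    expected, so a lone error does not pass as hypermutation).  Stop codons
    tabulate as '*'.  Reads not covering the codon are skipped and counted.
    """
    ref = db[allele]
    off = imgt_codon_to_ungapped_offset(ref, imgt_codon)
    germ_codon = ref.sequence_ungapped[off:off + 3]
    germ_res = str(Seq(germ_codon).translate())
    sub = annotated[annotated["v_unique"]
                    & (annotated["v_call"] == allele)
                    & annotated["productive"]
                    & (annotated["v_mismatches"] >= min_mutations)]
    counts: dict[str, int] = {}
    skipped = 0
    if "sequence" not in sub.columns:
        raise ValueError("annotated frame must retain a 'sequence' column "
                         "for codon profiling")
    for seq in sub["sequence"]:
        codon = seq[off:off + 3]
        if len(codon) < 3:
            skipped += 1
            continue
        res = str(Seq(codon).translate())
        counts[res] = counts.get(res, 0) + 1
    ctx = hotspot_context(ref.sequence_ungapped, off)
    return CodonSubstitutionProfile(
        allele=allele, imgt_codon=imgt_codon, germline_residue=germ_res,
        residue_counts=counts, hotspot_context=ctx,
        n_skipped_no_coverage=skipped)
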