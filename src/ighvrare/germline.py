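"""Germline segment reference handling.

Loads V/D/J germline allele sequences (plain or IMGT-gapped FASTA), keeps
them keyed by standardized allele names (``GENE*NN``), and provides the
pairwise-mismatch and nearest-neighbor queries that drive reasoning about
read misassignment between near-identical alleles.

Coordinate conventions: IMGT positions are 1-based and refer to the gapped
alignment; all internal offsets are 0-based.  Conversions between the two
live in this module only.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "GermlineAllele",
    "GermlineDatabase",
    "load_germline_fasta",
    "write_germline_fasta",
    "pairwise_mismatch",
    "nearest_neighbor",
]

_VALID_BASES = frozenset("ACGT")
_ALLELE_RE = re.compile(r"^(?P<gene>IGH[VDJ][\w.\-/]*)\*(?P<suffix>\w{2})$")


@dataclass(frozen=True)
class GermlineAllele:
    """One germline segment allele.

    ``anchor_offset`` is the 0-based offset of the first base of the
    conserved 2nd-CYS codon (IMGT 104) for V segments, or of the conserved
    J-TRP/J-PHE codon (IMGT 118) for J segments, in the ungapped sequence.
    """

    name: str
    sequence_ungapped: str
    sequence_gapped: str | None = None
    anchor_offset: int | None = None

    def __post_init__(self) -> None:
        m = _ALLELE_RE.match(self.name)
        if m is None:
            raise ValueError(f"allele name {self.name!r} does not parse as GENE*NN")
        if not self.sequence_ungapped:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.sequence_ungapped) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.name}: non-ACGT character(s) {sorted(bad)}")
        if self.sequence_gapped is not None:
            if self.sequence_gapped.replace(".", "") != self.sequence_ungapped:
                raise ValueError(
                    f"{self.name}: gapped sequence with dots removed does not "
                    "equal the ungapped sequence"
                )
        if self.anchor_offset is not None:
            if not 0 <= self.anchor_offset <= len(self.sequence_ungapped) - 3:
                raise ValueError(f"{self.name}: anchor_offset out of sequence bounds")
            if self.segment == "V" and self.anchor_offset % 3 != 0:
                raise ValueError(f"{self.name}: V anchor_offset must be in-frame")

    @property
    def gene(self) -> str:
        return self.name.split("*")[0]

    @property
    def segment(self) -> str:
        """'V', 'D' or 'J', inferred from the gene name."""
        return self.name[3]

    @property
    def subgroup(self) -> str:
        m = re.match(r"(IGH[VDJ]\d+)", self.name)
        return m.group(1) if m else self.gene

    def __len__(self) -> int:
        return len(self.sequence_ungapped)


class GermlineDatabase:
    """Collection of :class:`GermlineAllele` keyed by unique name."""

    def __init__(self, alleles: Iterable[GermlineAllele] = ()) -> None:
        self._alleles: dict[str, GermlineAllele] = {}
        for a in alleles:
            self.add(a)

    def add(self, allele: GermlineAllele) -> None:
        if allele.name in self._alleles:
            raise ValueError(f"duplicate allele name: {allele.name}")
        self._alleles[allele.name] = allele

    def __getitem__(self, name: str) -> GermlineAllele:
        return self._alleles[name]

    def __contains__(self, name: str) -> bool:
        return name in self._alleles

    def __iter__(self) -> Iterator[GermlineAllele]:
        return iter(self._alleles.values())

    def __len__(self) -> int:
        return len(self._alleles)

    @property
    def names(self) -> list[str]:
        return list(self._alleles)

    def by_segment(self, segment: str) -> list[GermlineAllele]:
        return [a for a in self if a.segment == segment]

    def by_gene(self, gene: str) -> list[GermlineAllele]:
        return [a for a in self if a.gene == gene]

    def segment_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self:
            out[a.segment] = out.get(a.segment, 0) + 1
        return out

    def validate_for_haplotyping(self) -> None:
        """At least one V allele and two IGHJ6 alleles are required to
        anchor V alleles to chromosomes via IGHJ6 heterozygosity."""
        if not self.by_segment("V"):
            raise ValueError("database holds no V alleles")
        if len(self.by_gene("IGHJ6")) < 2:
            raise ValueError("haplotyping requires >=2 IGHJ6 alleles")


def _parse_header(header: str) -> str:
    """Extract the allele-name token from a FASTA header.

    Accepts plain ``IGHV1-2*05`` headers and IMGT pipe-delimited headers
    where the allele name is the second field.
    """
    for token in header.split("|"):
        token = token.strip().split()[0] if token.strip() else token
        if _ALLELE_RE.match(token):
            return token
    raise ValueError(f"no allele name token found in header {header!r}")


def load_germline_fasta(path: str | Path) -> GermlineDatabase:
    """Read a germline reference FASTA (plain or gzip; '.' marks IMGT gaps).

    Segment is inferred from the gene name; a sequence containing '.' is
    treated as IMGT-gapped and both gapped and ungapped forms are stored.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    db = GermlineDatabase()
    with opener(path, "rt") as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            try:
                name = _parse_header(rec.description)
            except ValueError as exc:
                raise ValueError(f"record {i}: {exc}") from exc
            seq = str(rec.seq).upper()
            gapped = seq if "." in seq else None
            ungapped = seq.replace(".", "")
            bad = set(ungapped) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"record {i} ({name}): non-ACGT. character(s) {sorted(bad)}"
                )
            anchor = None
            m = re.search(r"\banchor=(\d+)\b", rec.description)
            if m:
                anchor = int(m.group(1))
            db.add(GermlineAllele(name=name, sequence_ungapped=ungapped,
                                  sequence_gapped=gapped, anchor_offset=anchor))
    return db


def write_germline_fasta(db: GermlineDatabase, path: str | Path) -> None:
    """Write a reference FASTA (gapped form when present).  Anchor offsets
    are carried in the header as ``anchor=<0-based ungapped offset>`` so a
    written database round-trips through :func:`load_germline_fasta`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for a in db:
            header = a.name
            if a.anchor_offset is not None:
                header += f" anchor={a.anchor_offset}"
            fh.write(f">{header}\n{a.sequence_gapped or a.sequence_ungapped}\n")


def pairwise_mismatch(
    a: GermlineAllele, b: GermlineAllele
) -> tuple[int, list[int]]:
    """Mismatch count and differing positions between two same-segment alleles.

    When both alleles carry an IMGT-gapped sequence the comparison runs over
    the gapped alignment and positions are reported 1-based in IMGT
    coordinates; positions where either allele has a gap are skipped.
    Otherwise the comparison runs over the leading overlap of the ungapped
    sequences (5'RACE reads and references share the 5' start) and positions
    are 1-based in that overlap.
    """
    if a.segment != b.segment:
        raise ValueError(f"segment mismatch: {a.name} ({a.segment}) vs "
                         f"{b.name} ({b.segment})")
    if a.sequence_gapped is not None and b.sequence_gapped is not None:
        sa, sb = a.sequence_gapped, b.sequence_gapped
        span = min(len(sa), len(sb))
        positions = [
            i + 1
            for i in range(span)
            if sa[i] != "." and sb[i] != "." and sa[i] != sb[i]
        ]
    else:
        sa, sb = a.sequence_ungapped, b.sequence_ungapped
        span = min(len(sa), len(sb))
        positions = [i + 1 for i in range(span) if sa[i] != sb[i]]
    return len(positions), positions


def nearest_neighbor(
    allele: GermlineAllele, db: GermlineDatabase
) -> tuple[str, int]:
    """The most similar other allele of the same segment, with its distance.

    Ties are broken by lexicographic allele name so the answer is
    deterministic across runs.
    """
    candidates = [a for a in db.by_segment(allele.segment) if a.name != allele.name]
    if not candidates:
        raise ValueError(f"no other {allele.segment} allele in database to "
                         f"compare {allele.name} against")
    best_name, best_dist = None, None
    for other in sorted(candidates, key=lambda a: a.name):
        dist, _ = pairwise_mismatch(allele, other)
        if best_dist is None or dist < best_dist:
            best_name, best_dist = other.name, dist
    return best_name, best_dist
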