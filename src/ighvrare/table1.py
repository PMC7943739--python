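"""Cohort genotype table: per-dataset allele calls for the four focal genes.

The bundled fixture transcribes the study cohort's genotype table: 35
IGHJ6-heterozygous (haplotypable) datasets with, for each of IGHV1-2,
IGHV1-3, IGHV4-4 and IGHV7-4-1, the alleles reported by the inference tool
and the alleles supported by read-level analysis.  Footnote markers on
inferred alleles (tentative inferences dropped by the tool's final filter)
are preserved as flags but consumed by no operation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import pandas as pd

__all__ = [
    "GENES",
    "GenotypeTable",
    "load_genotype_table",
    "bundled_table_path",
    "genotype_table_summary",
]

GENES = ("IGHV1-2", "IGHV1-3", "IGHV4-4", "IGHV7-4-1")
_MARKERS = "†¶§"
_TOKEN_RE = re.compile(r"^\*(?P<suffix>\w{2})(?P<flags>[†¶§]*)$")


@dataclass
class GenotypeCell:
    alleles: list[str] = field(default_factory=list)  # full names GENE*NN
    flags: dict[str, str] = field(default_factory=dict)  # allele -> markers


@dataclass
class GenotypeRow:
    dataset_id: str
    n_reads: int
    inferred: dict[str, GenotypeCell] = field(default_factory=dict)
    read_level: dict[str, GenotypeCell] = field(default_factory=dict)


@dataclass
class GenotypeTable:
    rows: list[GenotypeRow]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Serialize back to the fixture's TSV layout (round-trip safe)."""
        out = []
        for r in self.rows:
            row = {"dataset_id": r.dataset_id, "n_reads": r.n_reads}
            for gene in GENES:
                for kind, cells in (("inferred", r.inferred),
                                    ("read", r.read_level)):
                    cell = cells[gene]
                    row[f"{gene}_{kind}"] = ", ".join(
                        "*" + a.split("*")[1] + cell.flags.get(a, "")
                        for a in cell.alleles)
            out.append(row)
        return pd.DataFrame(out)


def _parse_cell(gene: str, text: str, dataset_id: str) -> GenotypeCell:
    cell = GenotypeCell()
    text = text.strip()
    if not text:
        return cell
    for token in re.split(r"[,\s]+", text):
        if not token:
            continue
        m = _TOKEN_RE.match(token)
        if m is None:
            raise ValueError(
                f"dataset {dataset_id}: malformed allele token {token!r} "
                f"in {gene} column")
        name = f"{gene}*{m.group('suffix')}"
        cell.alleles.append(name)
        if m.group("flags"):
            cell.flags[name] = m.group("flags")
    return cell


def bundled_table_path() -> Path:
    return Path(str(resources.files("ighvrare").joinpath("data/table1.tsv")))


def load_genotype_table(path: str | Path | None = None) -> GenotypeTable:
    """Parse the genotype table TSV (the bundled fixture by default)."""
    path = bundled_table_path() if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    seen: set[str] = set()
    for _, rec in df.iterrows():
        sid = rec["dataset_id"]
        if sid in seen:
            raise ValueError(f"duplicate dataset_id {sid}")
        seen.add(sid)
        row = GenotypeRow(dataset_id=sid, n_reads=int(rec["n_reads"]))
        for gene in GENES:
            row.inferred[gene] = _parse_cell(gene, rec[f"{gene}_inferred"], sid)
            row.read_level[gene] = _parse_cell(gene, rec[f"{gene}_read"], sid)
        rows.append(row)
    return GenotypeTable(rows)


@dataclass
class GenotypeTableSummary:
    n_datasets: int
    allele_counts: dict[str, int]          # read-level call column
    gene_no_call: dict[str, int]           # both columns empty
    cooccurrence: dict[tuple[str, str], int]  # read-level, unordered pairs

    def count(self, allele: str) -> int:
        return self.allele_counts.get(allele, 0)

    def cooccur(self, a: str, b: str) -> int:
        if a == b:
            return self.count(a)
        key = tuple(sorted((a, b)))
        return self.cooccurrence.get(key, 0)


def genotype_table_summary(table: GenotypeTable) -> GenotypeTableSummary:
    """Exact integer counts over the genotype table.

    Per allele: datasets whose read-level column lists it.  Per gene:
    datasets where both the inference and the read-level columns are empty
    (no call at all).  Pairwise co-occurrence is defined on the read-level
    columns.
    """
    allele_counts: dict[str, int] = {}
    gene_no_call: dict[str, int] = {g: 0 for g in GENES}
    cooc: dict[tuple[str, str], int] = {}
    for row in table.rows:
        present: set[str] = set()
        for gene in GENES:
            present |= set(row.read_level[gene].alleles)
            if not row.inferred[gene].alleles and not row.read_level[gene].alleles:
                gene_no_call[gene] += 1
        for a in present:
            allele_counts[a] = allele_counts.get(a, 0) + 1
        for a, b in combinations(sorted(present), 2):
            cooc[(a, b)] = cooc.get((a, b), 0) + 1
    return GenotypeTableSummary(
        n_datasets=len(table.rows),
        allele_counts=allele_counts,
        gene_no_call=gene_no_call,
        cooccurrence=cooc,
    )
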