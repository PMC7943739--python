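"""Read annotation: unique V/J allele assignment, junction, productivity.

Implements the subset of repertoire annotation the rare-allele analysis
depends on: each read is compared against every germline V allele over the
leading overlap (5'-anchored, ungapped, substitution-only) and against every
J allele anchored at the read's 3' end (with a small offset search); a read
is *uniquely* assigned only when a single allele attains the minimal
mismatch count among alleles surviving a mismatch-fraction cutoff.
Ambiguous reads are retained and flagged, never silently dropped — they
stay in the per-file read total that serves as the frequency denominator.

Uniqueness here is threshold-free among survivors: duplicating the best
allele under a new name always breaks uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .germline import GermlineAllele, GermlineDatabase

__all__ = [
    "AnnotatedRearrangement",
    "assign_v",
    "assign_j",
    "extract_junction",
    "call_productivity",
    "annotate_reads",
    "annotate_sequences",
    "write_annotated_tsv",
    "read_annotated_tsv",
]

MIN_READ_LENGTH = 100  # minimum V-region coverage required for assignment
DEFAULT_MAX_MISMATCH_FRAC = 0.10
J_OFFSET_SEARCH = 6  # 3'-end offsets tried when anchoring J references

_STOP_CODES = (48, 50, 56)  # TAA, TAG, TGA with A,C,G,T -> 0..3, base-4


@dataclass
class AnnotatedRearrangement:
    """One read's allele calls, uniqueness, junction and productivity."""

    read_id: str
    v_candidates: list[tuple[str, int]]
    v_unique: bool
    v_call: str | None
    v_mismatches: int | None
    j_candidates: list[tuple[str, int]]
    j_unique: bool
    j_call: str | None
    junction: str | None
    junction_length: int | None
    cdr3_length: int | None
    in_frame: bool
    has_stop: bool
    productive: bool
    flag: str  # "", "too_short", "ambiguous", "anchor_lost"


def _encode(seqs: list[str], width: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack sequences into a (n, width) uint8 matrix of base codes 0..3;
    positions beyond a read's length hold 255.  Returns (matrix, lengths)."""
    n = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    mat = np.full((n, width), 255, dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    for i, s in enumerate(seqs):
        arr = np.frombuffer(s[:width].encode(), dtype=np.uint8)
        mat[i, : len(arr)] = lut[arr]
    return mat, lengths


def _v_mismatch_table(
    seqs: list[str], v_alleles: list[GermlineAllele], max_mismatch_frac: float
) -> np.ndarray:
    """(n_reads, n_alleles) mismatch counts over leading overlaps; np.inf
    where an allele is discarded by the mismatch-fraction cutoff."""
    width = max(len(a) for a in v_alleles)
    mat, lengths = _encode(seqs, width)
    out = np.full((len(seqs), len(v_alleles)), np.inf)
    for k, allele in enumerate(v_alleles):
        ref, _ = _encode([allele.sequence_ungapped], len(allele))
        ref = ref[0]
        L = len(allele)
        diff = (mat[:, :L] != ref[None, :]).sum(axis=1)
        overhang = np.maximum(0, L - lengths)  # padding counted as mismatch
        mism = diff - overhang
        compared = np.minimum(lengths, L)
        ok = mism <= max_mismatch_frac * compared
        out[ok, k] = mism[ok]
    return out


def _j_mismatch_table(
    seqs: list[str], j_alleles: list[GermlineAllele], max_mismatch_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Best (over 3'-end offsets 0..J_OFFSET_SEARCH) mismatch count of each
    J allele against each read suffix, over the full J length.

    Returns (mismatch table with np.inf for discarded, best-offset table).
    """
    n = len(seqs)
    out = np.full((n, len(j_alleles)), np.inf)
    offs = np.zeros((n, len(j_alleles)), dtype=np.int64)
    # right-aligned encoding: last base of read at the last column
    width = max(len(a) for a in j_alleles) + J_OFFSET_SEARCH
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    mat = np.full((n, width), 255, dtype=np.uint8)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    for i, s in enumerate(seqs):
        tail = s[-width:]
        arr = lut[np.frombuffer(tail.encode(), dtype=np.uint8)]
        mat[i, width - len(arr):] = arr
    for k, allele in enumerate(j_alleles):
        L = len(allele)
        ref = lut[np.frombuffer(allele.sequence_ungapped.encode(), dtype=np.uint8)]
        best = np.full(n, np.inf)
        best_off = np.zeros(n, dtype=np.int64)
        for off in range(J_OFFSET_SEARCH + 1):
            lo = width - L - off
            hi = width - off if off else width
            window = mat[:, lo:hi]
            mism = (window != ref[None, :]).sum(axis=1).astype(float)
            mism[lengths < L + off] = np.inf  # J must fit in the read
            better = mism < best
            best[better] = mism[better]
            best_off[better] = off
        ok = best <= max_mismatch_frac * L
        out[ok, k] = best[ok]
        offs[:, k] = best_off
    return out, offs


def _minimal_set(row: np.ndarray, names: list[str]) -> list[tuple[str, int]]:
    m = row.min()
    if not np.isfinite(m):
        return []
    return [(names[k], int(row[k])) for k in np.flatnonzero(row == m)]


def assign_v(
    sequence: str,
    db: GermlineDatabase,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[tuple[str, int]], bool]:
    """Candidate V alleles at minimal mismatch, and whether the minimum is
    attained by a single allele (the read is then unequivocally assigned)."""
    v_alleles = db.by_segment("V")
    if not v_alleles:
        raise ValueError("no V alleles in database")
    table = _v_mismatch_table([sequence], v_alleles, max_mismatch_frac)
    cands = _minimal_set(table[0], [a.name for a in v_alleles])
    return cands, len(cands) == 1


def assign_j(
    sequence: str,
    db: GermlineDatabase,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[tuple[str, int]], bool]:
    """3'-anchored J assignment with the same uniqueness rule as assign_v."""
    j_alleles = db.by_segment("J")
    if not j_alleles:
        raise ValueError("no J alleles in database")
    table, _ = _j_mismatch_table([sequence], j_alleles, max_mismatch_frac)
    cands = _minimal_set(table[0], [a.name for a in j_alleles])
    return cands, len(cands) == 1


def extract_junction(
    sequence: str,
    v_call: str,
    j_call: str,
    db: GermlineDatabase,
    j_offset: int = 0,
) -> tuple[str | None, int | None]:
    """Junction from the V 2nd-CYS codon through the J-TRP codon, inclusive.

    Returns (junction, junction_length), or (None, None) when either anchor
    falls outside the read ("anchor_lost").
    """
    v = db[v_call]
    j = db[j_call]
    if v.anchor_offset is None or j.anchor_offset is None:
        raise ValueError("anchor offsets required on both V and J alleles")
    js = v.anchor_offset
    je = len(sequence) - j_offset - (len(j) - j.anchor_offset - 3)
    if js + 6 <= je <= len(sequence):
        junction = sequence[js:je]
        return junction, len(junction)
    return None, None


def call_productivity(
    in_frame: bool, has_stop: bool, anchors_ok: bool
) -> bool:
    """Productive = in-frame, stop-free from V codon 1 through the J end,
    with both junction anchors located."""
    return bool(in_frame and not has_stop and anchors_ok)


def _stop_scan(seqs: list[str], stop_limits: np.ndarray) -> np.ndarray:
    """Vectorized frame-0 stop-codon scan of each read up to its limit
    (the end of the aligned J segment)."""
    width = int(max(len(s) for s in seqs))
    mat, lengths = _encode(seqs, width)
    n_codons = width // 3
    cod = mat[:, : n_codons * 3].reshape(len(seqs), n_codons, 3).astype(np.int16)
    val = cod[:, :, 0] * 16 + cod[:, :, 1] * 4 + cod[:, :, 2]
    is_stop = np.isin(val, _STOP_CODES)
    limit = np.minimum(lengths, stop_limits)
    codon_idx = np.arange(n_codons) * 3
    in_range = codon_idx[None, :] + 3 <= limit[:, None]
    return (is_stop & in_range).any(axis=1)


def annotate_sequences(
    ids: list[str],
    seqs: list[str],
    db: GermlineDatabase,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> pd.DataFrame:
    """Annotate a batch of reads; the workhorse behind annotate_reads.

    Every read lands in exactly one accounting bucket: ``unique`` (uniquely
    V- and J-assigned, anchors intact), ``ambiguous``, ``too_short`` or
    ``anchor_lost``.
    """
    n = len(seqs)
    v_alleles = db.by_segment("V")
    j_alleles = db.by_segment("J")
    v_names = [a.name for a in v_alleles]
    j_names = [a.name for a in j_alleles]

    too_short = np.array([len(s) < MIN_READ_LENGTH for s in seqs])
    v_table = _v_mismatch_table(seqs, v_alleles, max_mismatch_frac)
    j_table, j_offs = _j_mismatch_table(seqs, j_alleles, max_mismatch_frac)

    v_min = v_table.min(axis=1)
    v_ties = (v_table == v_min[:, None]).sum(axis=1)
    v_uniq = np.isfinite(v_min) & (v_ties == 1) & ~too_short
    v_best = v_table.argmin(axis=1)
    j_min = j_table.min(axis=1)
    j_ties = (j_table == j_min[:, None]).sum(axis=1)
    j_uniq = np.isfinite(j_min) & (j_ties == 1) & ~too_short
    j_best = j_table.argmin(axis=1)

    rows = []
    junctions: list[str | None] = []
    stop_limits = np.zeros(n, dtype=np.int64)
    anchors_ok = np.zeros(n, dtype=bool)
    for i in range(n):
        if v_uniq[i] and j_uniq[i]:
            off = int(j_offs[i, j_best[i]])
            junction, _ = extract_junction(
                seqs[i], v_names[v_best[i]], j_names[j_best[i]], db, off)
            junctions.append(junction)
            anchors_ok[i] = junction is not None
            stop_limits[i] = len(seqs[i]) - off
        else:
            junctions.append(None)
            stop_limits[i] = len(seqs[i])
    has_stop = _stop_scan(seqs, stop_limits)

    for i in range(n):
        v_cands = _minimal_set(v_table[i], v_names) if not too_short[i] else []
        j_cands = _minimal_set(j_table[i], j_names) if not too_short[i] else []
        junction = junctions[i]
        jl = len(junction) if junction is not None else None
        in_frame = jl is not None and jl % 3 == 0
        productive = call_productivity(in_frame, bool(has_stop[i]),
                                       bool(anchors_ok[i]))
        if too_short[i]:
            flag = "too_short"
        elif not (v_uniq[i] and j_uniq[i]):
            flag = "ambiguous"
        elif not anchors_ok[i]:
            flag = "anchor_lost"
        else:
            flag = ""
        rows.append({
            "sequence_id": ids[i],
            "sequence": seqs[i],
            "v_call": v_names[v_best[i]] if v_uniq[i] else "",
            "v_unique": bool(v_uniq[i]),
            "v_mismatches": int(v_table[i, v_best[i]]) if v_uniq[i] else -1,
            "v_candidates": ";".join(f"{nm}:{m}" for nm, m in v_cands),
            "j_call": j_names[j_best[i]] if j_uniq[i] else "",
            "j_unique": bool(j_uniq[i]),
            "junction": junction or "",
            "junction_length": jl if jl is not None else -1,
            "cdr3_length": jl - 6 if jl is not None else -1,
            "in_frame": bool(in_frame),
            "has_stop": bool(has_stop[i]),
            "productive": bool(productive),
            "flag": flag,
        })
    return pd.DataFrame(rows)


def annotate_reads(
    reads_path: str | Path,
    db: GermlineDatabase,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> pd.DataFrame:
    """Annotate reads from a FASTA file or an AIRR TSV with a sequence column."""
    reads_path = Path(reads_path)
    if reads_path.suffix in (".fasta", ".fa", ".fna"):
        recs = list(SeqIO.parse(str(reads_path), "fasta"))
        ids = [r.id for r in recs]
        seqs = [str(r.seq).upper() for r in recs]
    else:
        df = pd.read_csv(reads_path, sep="\t", dtype=str, keep_default_na=False)
        if "sequence" not in df.columns:
            raise ValueError(f"{reads_path}: no 'sequence' column")
        ids = list(df.get("sequence_id", df.index.astype(str)))
        seqs = [s.upper() for s in df["sequence"]]
    return annotate_sequences(ids, seqs, db, max_mismatch_frac)


_AIRR_OUT_COLUMNS = [
    "sequence_id", "sequence", "v_call", "j_call", "junction",
    "junction_length", "productive", "v_unique", "v_mismatches",
    "cdr3_length", "flag",
]


def write_annotated_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """AIRR Rearrangement TSV with this package's extension columns."""
    out = df.copy()
    out["productive"] = out["productive"].map({True: "T", False: "F"})
    out["v_unique"] = out["v_unique"].map({True: "T", False: "F"})
    out[_AIRR_OUT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotated_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["productive"] = df["productive"] == "T"
    df["v_unique"] = df["v_unique"] == "T"
    for col in ("junction_length", "cdr3_length", "v_mismatches"):
        df[col] = df[col].astype(int)
    df["j_unique"] = df["j_call"] != ""
    df["in_frame"] = (df["junction_length"] >= 0) & (df["junction_length"] % 3 == 0)
    return df
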