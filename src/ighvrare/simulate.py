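"""Synthetic AIRR repertoire simulation with full ground truth.

Emulates 5'RACE full-length heavy-chain repertoires: every read starts at
the first base of its V gene, runs through a V(D)J junction with exonuclease
trimming and random N additions, and ends at the 3' end of the J gene.
Per-haplotype V expression weights span the full dynamic range the analysis
cares about (majors at percent level down to poorly expressed alleles at a
few hundredths of a percent of reads), out-of-frame passenger rearrangements
are generated at a controlled rate, and somatic hypermutation and sequencing
error are applied as independent per-base substitution processes.

Indels are not simulated; the downstream annotator assumes
substitution-only divergence (a documented scope limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .germline import GermlineDatabase

__all__ = [
    "HaplotypeSpec",
    "SubjectSpec",
    "SimulatedRead",
    "SimulationLog",
    "simulate_repertoire",
    "write_repertoire",
    "read_airr_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

AIRR_COLUMNS = [
    "sequence_id", "sequence", "v_call", "d_call", "j_call",
    "junction", "junction_length", "productive",
]


@dataclass
class HaplotypeSpec:
    """Expression model of one chromosome 14 copy.

    ``v_expression`` maps V allele name -> relative transcript weight
    (0 or absence = deleted/silent); ``j6_allele`` is the IGHJ6 allele this
    chromosome carries; ``j_other_usage`` is the probability that a
    rearrangement uses a non-IGHJ6 J gene.
    """

    haplotype_id: str  # "H1" or "H2"
    v_expression: dict[str, float]
    j6_allele: str
    j_other_usage: float = 0.3

    def __post_init__(self) -> None:
        if self.haplotype_id not in ("H1", "H2"):
            raise ValueError("haplotype_id must be 'H1' or 'H2'")
        weights = [w for w in self.v_expression.values()]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("v_expression weights must be >=0 with at least "
                             "one positive")
        if not 0 <= self.j_other_usage < 1:
            raise ValueError("j_other_usage must be in [0, 1)")


@dataclass
class SubjectSpec:
    subject_id: str
    haplotypes: tuple[HaplotypeSpec, HaplotypeSpec]
    n_reads: int
    shm_rate: float = 0.0
    seq_error_rate: float = 0.0
    trim_mean: float = 2.0
    n_insert_max: int = 8
    passenger_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for r in (self.shm_rate, self.seq_error_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("rates must be in [0, 0.2]")
        if not 0 <= self.passenger_fraction <= 1:
            raise ValueError("passenger_fraction must be in [0, 1]")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    true_haplotype: str
    true_v: str
    true_d: str
    true_j: str
    true_junction: str
    true_in_frame: bool
    true_has_stop: bool
    mutated_positions: list[int] = field(default_factory=list)
    error_positions: list[int] = field(default_factory=list)


@dataclass
class SimulationLog:
    n_reads: int = 0
    frame_redraw_exhausted: int = 0


def _geometric0(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Geometric draw on {0, 1, ...} with the given mean."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    return rng.geometric(1.0 / (1.0 + mean), size) - 1


def _has_stop_in_frame(seq: str) -> bool:
    return any(seq[i:i + 3] in _STOPS for i in range(0, len(seq) - 2, 3))


def simulate_repertoire(
    spec: SubjectSpec,
    db: GermlineDatabase,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimulatedRead], SimulationLog]:
    """Draw a full repertoire for one subject.

    Bit-reproducible for a fixed ``spec.seed`` (when ``rng`` is not given).
    The junction composition (trims and N inserts) is redrawn until the
    read's frame matches a Bernoulli(1 - passenger_fraction) in-frame
    target, capped at 100 redraws per read.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    for hap in spec.haplotypes:
        for name in hap.v_expression:
            if name not in db:
                raise ValueError(f"allele {name} not in germline database")
        if hap.j6_allele not in db:
            raise ValueError(f"allele {hap.j6_allele} not in germline database")

    n = spec.n_reads
    log = SimulationLog(n_reads=n)

    # per-haplotype V sampling tables
    hap_tables = []
    for hap in spec.haplotypes:
        names = [k for k, w in hap.v_expression.items() if w > 0]
        probs = np.array([hap.v_expression[k] for k in names], dtype=float)
        hap_tables.append((names, probs / probs.sum()))

    d_alleles = db.by_segment("D")
    other_j = [a for a in db.by_segment("J") if a.gene != "IGHJ6"]
    if not d_alleles:
        raise ValueError("database holds no D alleles")

    hap_idx = rng.integers(0, 2, n)
    v_names = np.empty(n, dtype=object)
    for h in (0, 1):
        mask = hap_idx == h
        names, probs = hap_tables[h]
        v_names[mask] = rng.choice(names, size=int(mask.sum()), p=probs)
    use_j6 = rng.random(n) >= spec.haplotypes[0].j_other_usage \
        if spec.haplotypes[0].j_other_usage == spec.haplotypes[1].j_other_usage \
        else None
    if use_j6 is None:
        usage = np.array([spec.haplotypes[0].j_other_usage,
                          spec.haplotypes[1].j_other_usage])
        use_j6 = rng.random(n) >= usage[hap_idx]
    j_names = np.empty(n, dtype=object)
    for h in (0, 1):
        j_names[(hap_idx == h) & use_j6] = spec.haplotypes[h].j6_allele
    n_other = int((~use_j6).sum())
    if n_other and not other_j:
        raise ValueError("j_other_usage > 0 but no non-IGHJ6 J allele in db")
    if n_other:
        j_names[~use_j6] = rng.choice([a.name for a in other_j], size=n_other)
    d_names = rng.choice([a.name for a in d_alleles], size=n)

    v_tail = np.array([len(db[v]) - db[v].anchor_offset - 3 for v in v_names])
    d_len = np.array([len(db[d]) for d in d_names])
    j_anchor = np.array([db[j].anchor_offset for j in j_names])
    target_in_frame = rng.random(n) < 1.0 - spec.passenger_fraction

    def draw_junction(size: int, vt, dl, ja):
        tv = np.minimum(_geometric0(rng, spec.trim_mean, size), vt)
        tj = np.minimum(_geometric0(rng, spec.trim_mean, size), ja)
        td5 = np.minimum(_geometric0(rng, spec.trim_mean, size), dl)
        td3 = np.minimum(_geometric0(rng, spec.trim_mean, size), dl - td5)
        n1 = rng.integers(0, spec.n_insert_max + 1, size)
        n2 = rng.integers(0, spec.n_insert_max + 1, size)
        return tv, tj, td5, td3, n1, n2

    tv, tj, td5, td3, n1, n2 = draw_junction(n, v_tail, d_len, j_anchor)
    jl = (3 + v_tail - tv) + n1 + (d_len - td5 - td3) + n2 + (j_anchor - tj + 3)
    active = ((jl % 3 == 0) != target_in_frame)
    for _ in range(100):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        draws = draw_junction(len(idx), v_tail[idx], d_len[idx], j_anchor[idx])
        tv[idx], tj[idx], td5[idx], td3[idx], n1[idx], n2[idx] = draws
        jl[idx] = ((3 + v_tail[idx] - tv[idx]) + n1[idx]
                   + (d_len[idx] - td5[idx] - td3[idx]) + n2[idx]
                   + (j_anchor[idx] - tj[idx] + 3))
        active = ((jl % 3 == 0) != target_in_frame)
    log.frame_redraw_exhausted = int(active.sum())

    reads: list[SimulatedRead] = []
    for i in range(n):
        v = db[v_names[i]]
        d = db[d_names[i]]
        j = db[j_names[i]]
        ins1 = "".join("ACGT"[b] for b in rng.integers(0, 4, n1[i]))
        ins2 = "".join("ACGT"[b] for b in rng.integers(0, 4, n2[i]))
        v_part = v.sequence_ungapped[: len(v) - tv[i]]
        d_part = d.sequence_ungapped[td5[i]: len(d) - td3[i]]
        j_part = j.sequence_ungapped[tj[i]:]
        seq = v_part + ins1 + d_part + ins2 + j_part
        js = v.anchor_offset
        je = len(seq) - (len(j) - j.anchor_offset - 3)
        junction = seq[js:je]
        in_frame = len(junction) % 3 == 0
        has_stop = _has_stop_in_frame(seq)

        mut_pos: list[int] = []
        err_pos: list[int] = []
        if spec.shm_rate > 0 or spec.seq_error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            code = np.searchsorted(_BASES, arr)  # ACGT are sorted bytes
            for rate, store in ((spec.shm_rate, mut_pos),
                                (spec.seq_error_rate, err_pos)):
                if rate > 0:
                    hits = np.flatnonzero(rng.random(len(seq)) < rate)
                    if len(hits):
                        code[hits] = (code[hits]
                                      + rng.integers(1, 4, len(hits))) % 4
                        store.extend(int(p) for p in hits)
            mutated = _BASES[code].tobytes().decode()
        else:
            mutated = seq

        reads.append(SimulatedRead(
            read_id=f"{spec.subject_id}_r{i:06d}",
            sequence=mutated,
            true_haplotype=f"H{hap_idx[i] + 1}",
            true_v=v.name, true_d=d.name, true_j=j.name,
            true_junction=junction,
            true_in_frame=bool(in_frame),
            true_has_stop=bool(has_stop),
            mutated_positions=mut_pos,
            error_positions=err_pos,
        ))
    return reads, log


def write_repertoire(
    reads: list[SimulatedRead],
    out_dir: str | Path,
    prefix: str = "repertoire",
    raw: bool = True,
) -> dict[str, Path]:
    """Write AIRR Rearrangement TSV, ground-truth TSV and read FASTA.

    With ``raw=True`` (the default) the AIRR file's call columns are left
    blank — annotation is the annotator's job; truth-derived calls live in
    the truth file only.
    """
    if not reads:
        raise ValueError("no reads to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    airr = pd.DataFrame({
        "sequence_id": [r.read_id for r in reads],
        "sequence": [r.sequence for r in reads],
        "v_call": "" if raw else [r.true_v for r in reads],
        "d_call": "" if raw else [r.true_d for r in reads],
        "j_call": "" if raw else [r.true_j for r in reads],
        "junction": "" if raw else [r.true_junction for r in reads],
        "junction_length": "" if raw else [len(r.true_junction) for r in reads],
        "productive": "" if raw else [
            "T" if r.true_in_frame and not r.true_has_stop else "F"
            for r in reads
        ],
    })[AIRR_COLUMNS]
    truth = pd.DataFrame({
        "sequence_id": [r.read_id for r in reads],
        "true_haplotype": [r.true_haplotype for r in reads],
        "true_v": [r.true_v for r in reads],
        "true_d": [r.true_d for r in reads],
        "true_j": [r.true_j for r in reads],
        "true_junction": [r.true_junction for r in reads],
        "junction_length": [len(r.true_junction) for r in reads],
        "true_in_frame": [r.true_in_frame for r in reads],
        "true_has_stop": [r.true_has_stop for r in reads],
        "n_shm": [len(r.mutated_positions) for r in reads],
        "n_seq_errors": [len(r.error_positions) for r in reads],
    })
    paths = {
        "airr": out_dir / f"{prefix}.airr.tsv",
        "truth": out_dir / f"{prefix}.truth.tsv",
        "fasta": out_dir / f"{prefix}.fasta",
    }
    airr.to_csv(paths["airr"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["fasta"], "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
    return paths


def read_airr_tsv(path: str | Path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV (round-trips write_repertoire output)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sequence_id" not in df.columns or "sequence" not in df.columns:
        raise ValueError(f"{path}: not an AIRR Rearrangement TSV "
                         "(missing sequence_id/sequence)")
    return df
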