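"""A compact synthetic immunoglobulin heavy-chain germline locus.

Builds a deterministic toy reference database whose *structure* mirrors the
real IGH locus features the analysis depends on: multi-allele V genes with
near-identical allele pairs (1-6 nt apart), IMGT-gapped V sequences with
the conserved 2nd-CYS codon at IMGT position 104, a short germline tail
past the CYS into CDR3 (so 3' trimming does not destroy the anchor), two
IGHJ6 alleles for haplotyping, and a focal codon (IMGT 92) engineered to
sit outside RGYW/WRCY and WA/TA hotspot motifs on one V gene, with its two
alleles one base apart at that codon.

Sequences themselves are random (stop-free in the V reading frame); only
the allele *relationships* are meaningful.  Allele names follow the genes
the synthetic locus emulates so that downstream tables read naturally.
"""

from __future__ import annotations

import numpy as np

from .germline import GermlineAllele, GermlineDatabase

__all__ = ["example_locus", "V_LEN", "V_ANCHOR", "GAP_RUNS"]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                if a + b + c not in _STOPS]

# V geometry: gapped length 318 nt (IMGT codons 1..106), two 9-nt gap runs,
# so the ungapped gene is 300 nt with the 2nd-CYS codon at offset 291 and a
# 6-nt germline tail into CDR3.
V_GAPPED_LEN = 318
GAP_RUNS = ((90, 99), (189, 198))  # gapped 0-based [start, stop) dot runs
V_LEN = V_GAPPED_LEN - sum(b - a for a, b in GAP_RUNS)
V_ANCHOR = 291  # ungapped offset of first base of the 2nd-CYS codon (IMGT 104)

_LOCUS_SEED = 20210224  # fixed: the reference content must be stable


def _random_orf(rng: np.random.Generator, n_codons: int) -> list[str]:
    return [
        _SAFE_CODONS[i]
        for i in rng.integers(0, len(_SAFE_CODONS), n_codons)
    ]


def _sub(seq: str, pos: int, base: str) -> str:
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1:]


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(0, 3)]


def _safe_point_mutation(rng: np.random.Generator, seq: str, codon_idx: int) -> str:
    """Substitute one base in the given codon without creating a stop."""
    for _ in range(50):
        off = codon_idx * 3 + rng.integers(0, 3)
        mutated = _sub(seq, off, _other_base(rng, seq[off]))
        if mutated[codon_idx * 3: codon_idx * 3 + 3] not in _STOPS:
            return mutated
    raise RuntimeError("could not place a stop-free point mutation")


def _gap(ungapped: str) -> str:
    """Insert the fixed IMGT-style gap runs into a 300-nt V sequence."""
    out, u = [], 0
    runs = iter(GAP_RUNS)
    nxt = next(runs, None)
    g = 0
    while g < V_GAPPED_LEN:
        if nxt is not None and g == nxt[0]:
            out.append("." * (nxt[1] - nxt[0]))
            g = nxt[1]
            nxt = next(runs, None)
        else:
            out.append(ungapped[u])
            u += 1
            g += 1
    return "".join(out)


def _v_base_gene(rng: np.random.Generator) -> str:
    codons = _random_orf(rng, V_LEN // 3)
    codons[97] = "TGT"  # 2nd-CYS (IMGT 104) at ungapped offset 291
    return "".join(codons)


def _make_v(name: str, ungapped: str) -> GermlineAllele:
    return GermlineAllele(name=name, sequence_ungapped=ungapped,
                          sequence_gapped=_gap(ungapped), anchor_offset=V_ANCHOR)


def example_locus() -> GermlineDatabase:
    """The bundled synthetic germline database (deterministic)."""
    rng = np.random.default_rng(_LOCUS_SEED)
    db = GermlineDatabase()

    # --- IGHV1-2: four alleles; *05 is the poorly expressed allele, *06 its
    # 1-nt nearest neighbor, *02/*04 are >=5 nt away from *05.
    b12 = _v_base_gene(rng)
    v12_02 = b12
    v12_04 = b12
    for c in (10, 40, 70):
        v12_04 = _safe_point_mutation(rng, v12_04, c)
    v12_05 = b12
    for c in (20, 45, 65, 75, 88):
        v12_05 = _safe_point_mutation(rng, v12_05, c)
    v12_06 = _safe_point_mutation(rng, v12_05, 52)
    db.add(_make_v("IGHV1-2*02", v12_02))
    db.add(_make_v("IGHV1-2*04", v12_04))
    db.add(_make_v("IGHV1-2*05", v12_05))
    db.add(_make_v("IGHV1-2*06", v12_06))

    # --- IGHV1-3: *01 common, *02 six bases away (poorly expressed).
    b13 = _v_base_gene(rng)
    v13_02 = b13
    for c in (2, 4, 35, 55, 69, 80):
        v13_02 = _safe_point_mutation(rng, v13_02, c)
    db.add(_make_v("IGHV1-3*01", b13))
    db.add(_make_v("IGHV1-3*02", v13_02))

    # --- IGHV4-4: *02/*07 common, *01 poorly expressed (4 nt from *02).
    b44 = _v_base_gene(rng)
    v44_07 = b44
    for c in (15, 42, 77):
        v44_07 = _safe_point_mutation(rng, v44_07, c)
    v44_01 = b44
    for c in (5, 30, 60, 90):
        v44_01 = _safe_point_mutation(rng, v44_01, c)
    db.add(_make_v("IGHV4-4*02", b44))
    db.add(_make_v("IGHV4-4*07", v44_07))
    db.add(_make_v("IGHV4-4*01", v44_01))

    # --- IGHV7-4-1: two alleles differing at one base, in the focal codon
    # (IMGT 92).  *01 carries the unusual cysteine (TGT); *02 serine (TCT).
    # The codon context (IMGT 91-93 = CCG TGT CGG) contains no RGYW/WRCY
    # 4-mer and no WA/TA 2-mer overlapping codon 92.
    b741 = _v_base_gene(rng)
    # IMGT codon c (1-based) -> ungapped codon index, past both gap runs
    # (gapped offset (c-1)*3 >= 198 -> subtract 18 nt = 6 codons).
    focal = "CCG" + "TGT" + "CGG"
    u0 = (91 - 1) * 3 - 18  # ungapped offset of IMGT codon 91
    v741_01 = b741[:u0] + focal + b741[u0 + 9:]
    v741_02 = _sub(v741_01, u0 + 4, "C")  # TGT -> TCT
    db.add(_make_v("IGHV7-4-1*01", v741_01))
    db.add(_make_v("IGHV7-4-1*02", v741_02))

    # --- filler single-allele V genes (highly expressed background).
    db.add(_make_v("IGHV3-23*01", _v_base_gene(rng)))
    db.add(_make_v("IGHV4-59*01", _v_base_gene(rng)))

    # --- D segments (never uniquely assigned; carried for completeness).
    for name, length in (("IGHD3-10*01", 21), ("IGHD2-2*01", 18),
                         ("IGHD6-19*01", 15)):
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, length))
        db.add(GermlineAllele(name=name, sequence_ungapped=seq))

    # --- J segments.  IGHJ6*02/*03 differ at two bases in the 3' half
    # (beyond typical 5' trimming); anchor = first base of the J-TRP codon.
    j6_codons = _random_orf(rng, 14)
    j6_codons[0] = "TGG"
    j6 = "".join(
        _BASES[i] for i in rng.integers(0, 4, 21)
    ) + "".join(j6_codons)  # 21 nt trimmable 5' region + 42 nt from TRP
    j6_03 = _safe_point_mutation(rng, j6[21:], 3)
    j6_03 = _safe_point_mutation(rng, j6_03, 9)
    db.add(GermlineAllele("IGHJ6*02", j6, anchor_offset=21))
    db.add(GermlineAllele("IGHJ6*03", j6[:21] + j6_03, anchor_offset=21))
    for name, lead, ncod in (("IGHJ4*02", 15, 11), ("IGHJ5*01", 18, 11)):
        codons = _random_orf(rng, ncod)
        codons[0] = "TGG"
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, lead)) + "".join(codons)
        db.add(GermlineAllele(name, seq, anchor_offset=lead))

    return db
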