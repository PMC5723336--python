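"""Translated homology recruitment of short reads to a marker gene.

Reads are six-frame translated and searched against the ungapped reference
amino-acid sequences by exhaustive local alignment (affine-gap
Smith-Waterman); significance is assessed with Karlin-Altschul statistics
(E = K*m*n*exp(-lambda*S)). Recruited reads are trimmed to the aligned
extent of the gene (removing up/downstream overhang), stops and
ambiguities are masked to 'X', and reads shorter than ``min_aa`` (default
33 amino acids, i.e. ~100 bp of coding sequence) are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _align
from .formats import SeqRecord
from .matrices import blosum_matrix, encode_aa
from .refpkg import ReferencePackage

CODON_TABLE_ID = 11

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = (1, 2, 3, -1, -2, -3)


def _codon_map() -> tuple[dict[str, str], set[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[CODON_TABLE_ID]
    return dict(table.forward_table), set(table.stop_codons)


_FORWARD, _STOPS = _codon_map()


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate frame +1 (bacterial/archaeal code, table 11); codons with
    ambiguities become 'X', stops '*', trailing partial codons dropped."""
    out = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3].upper()
        if codon in _FORWARD:
            out.append(_FORWARD[codon])
        elif codon in _STOPS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def six_frame_translate(dna: str) -> dict[int, str]:
    """All six reading frames; negative frames translate the reverse
    complement. Empty map for sequences shorter than one codon."""
    if len(dna) < 3:
        return {}
    rc = reverse_complement(dna)
    frames: dict[int, str] = {}
    for off in range(3):
        fwd = translate(dna[off:])
        if fwd:
            frames[off + 1] = fwd
        rev = translate(rc[off:])
        if rev:
            frames[-(off + 1)] = rev
    return frames


@dataclass
class ScoringScheme:
    """Protein scoring scheme with Karlin-Altschul calibration.

    Default lambda/K are the standard gapped BLOSUM62 (open 11 / extend 1)
    calibration; the search-space sizes m (query residues) and n (database
    residues) are filled in at search time.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_ext: float = 1.0
    lambda_: float = 0.267
    K: float = 0.041
    m: Optional[int] = None
    n: Optional[int] = None
    matrix: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be > 0")
        if self.gap_open < 0 or self.gap_ext < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.matrix is None:
            self.matrix = blosum_matrix(self.matrix_name)


def karlin_altschul_evalue(score: float, scheme: ScoringScheme) -> float:
    """Expected number of chance local alignments scoring >= ``score``."""
    if scheme.m is None or scheme.n is None:
        raise ValueError("search-space sizes m and n are not set")
    x = -scheme.lambda_ * score
    try:
        return scheme.K * scheme.m * scheme.n * math.exp(x)
    except OverflowError:
        return math.inf if x > 0 else 0.0


def smith_waterman(
    query_aa: str, ref_aa: str, scheme: ScoringScheme
) -> tuple[float, tuple[int, int], tuple[int, int], tuple[str, str]]:
    """Optimal local alignment; returns (score, query interval, reference
    interval, aligned pair with '-' gaps). Intervals are 0-based half-open."""
    if not query_aa or not ref_aa:
        raise ValueError("smith_waterman requires nonempty sequences")
    q = encode_aa(query_aa)
    r = encode_aa(ref_aa)
    score, qs, qe, rs, re_, ops, nops = _align.sw_traceback(
        q, r, scheme.matrix, scheme.gap_open, scheme.gap_ext
    )
    aq, ar = [], []
    i, j = qs, rs
    for k in range(nops):
        op = ops[k]
        if op == _align.OP_MATCH:
            aq.append(query_aa[i])
            ar.append(ref_aa[j])
            i += 1
            j += 1
        elif op == _align.OP_INS:
            aq.append(query_aa[i])
            ar.append("-")
            i += 1
        else:
            aq.append("-")
            ar.append(ref_aa[j])
            j += 1
    return float(score), (int(qs), int(qe)), (int(rs), int(re_)), (
        "".join(aq),
        "".join(ar),
    )


def merge_overlapping_pair(
    r1: SeqRecord,
    r2: SeqRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> Optional[SeqRecord]:
    """Merge a read pair whose fragments overlap.

    ``r2`` is reverse-complemented internally (it is supplied in
    sequencing orientation). The maximal suffix(r1)/prefix(revcomp r2)
    overlap of length >= ``min_overlap`` with mismatch fraction <=
    ``max_mismatch_frac`` wins; at mismatching positions the base from the
    higher-quality read is kept (ties favor r1). Returns None when no
    qualifying overlap exists.
    """
    s1 = r1.seq.upper()
    s2 = reverse_complement(r2.seq.upper())
    q1 = r1.qual if r1.qual is not None else [30] * len(s1)
    q2 = (r2.qual if r2.qual is not None else [30] * len(r2.seq))[::-1]
    max_olap = min(len(s1), len(s2))
    for olap in range(max_olap, min_overlap - 1, -1):
        tail = s1[len(s1) - olap :]
        head = s2[:olap]
        mismatches = sum(1 for a, b in zip(tail, head) if a != b)
        if mismatches / olap <= max_mismatch_frac:
            merged = list(s1 + s2[olap:])
            qual = list(q1 + q2[olap:])
            for k in range(olap):
                i1 = len(s1) - olap + k
                if tail[k] != head[k]:
                    if q2[k] > q1[i1]:
                        merged[i1] = head[k]
                        qual[i1] = q2[k]
                else:
                    qual[i1] = max(q1[i1], q2[k])
            return SeqRecord(r1.id, "".join(merged), qual)
    return None


@dataclass
class RecruitedRead:
    """A read trimmed to a gene's frame and extent, in amino-acid space."""

    read_id: str
    mate: str  # "1" | "2" | "merged"
    frame: int
    aa_seq: str
    dna_span: tuple[int, int]
    score: float
    evalue: float
    best_ref: str
    ref_span: tuple[int, int] = (0, 0)


def _mask_aa(seq: str) -> str:
    from .matrices import AA_INDEX

    return "".join(c if c.upper() in AA_INDEX else "X" for c in seq)


def recruit_and_trim(
    reads: list[SeqRecord],
    refpkg: ReferencePackage,
    scheme: Optional[ScoringScheme] = None,
    e_recruit: float = 1e-5,
    min_aa: int = 33,
    mate: str = "merged",
) -> list[RecruitedRead]:
    """Recruit reads to ``refpkg``'s gene and trim to frame and extent.

    For each read the best (frame, reference) pair is chosen by lowest
    e-value, ties broken by higher score then frame order +1,+2,+3,-1,-2,-3.
    The recruited amino-acid sequence is the locally aligned query interval
    (overhang beyond the gene removed by the local alignment itself), with
    stops/ambiguities masked to 'X'. Reads failing ``e_recruit`` or
    ``min_aa`` are dropped; each read yields at most one RecruitedRead.
    """
    if scheme is None:
        scheme = ScoringScheme()
    refs = refpkg.ungapped_references()
    if not refs:
        raise ValueError("reference set is empty")
    ref_codes = [np.where(encode_aa(r.seq) < 0, _align.PAD_CODE, encode_aa(r.seq))
                 for r in refs]
    n_db = sum(len(rc) for rc in ref_codes)
    mat21 = np.full((21, 21), _align.UNK_SCORE)
    mat21[:20, :20] = scheme.matrix

    # one work item per (read, frame); batched so the kernel vectorizes
    items: list[tuple[int, int, int, str]] = []  # (read idx, rank, frame, aa)
    frames_by_read: list[dict[int, str]] = []
    for ridx, read in enumerate(reads):
        frames = six_frame_translate(read.seq)
        frames_by_read.append(frames)
        for rank, fr in enumerate(FRAMES):
            aa = frames.get(fr)
            if aa:
                items.append((ridx, rank, fr, aa))
    scores = np.zeros((len(items), len(refs)))
    batch_size = 64
    order = sorted(range(len(items)), key=lambda t: -len(items[t][3]))
    for b0 in range(0, len(order), batch_size):
        chunk = order[b0 : b0 + batch_size]
        lmax = len(items[chunk[0]][3])
        QT = np.full((lmax, len(chunk)), _align.PAD_CODE, dtype=np.int64)
        for c, t in enumerate(chunk):
            codes = encode_aa(items[t][3])
            codes = np.where(codes < 0, _align.PAD_CODE, codes)
            QT[: len(codes), c] = codes
        for k, rc in enumerate(ref_codes):
            col = _align.sw_batch(QT, rc, mat21, scheme.gap_open, scheme.gap_ext)
            scores[chunk, k] = col

    # best (frame, ref) per read: lowest e-value, then highest score,
    # then frame order +1,+2,+3,-1,-2,-3
    best_by_read: dict[int, tuple] = {}
    for t, (ridx, rank, fr, aa) in enumerate(items):
        k = int(np.argmax(scores[t]))
        s = float(scores[t, k])
        ev = scheme.K * len(aa) * n_db * math.exp(-scheme.lambda_ * s)
        cand = (ev, -s, rank, k, fr, aa)
        prev = best_by_read.get(ridx)
        if prev is None or cand[:3] < prev[:3]:
            best_by_read[ridx] = cand

    out: list[RecruitedRead] = []
    for ridx, read in enumerate(reads):
        best = best_by_read.get(ridx)
        if best is None:
            continue
        ev, negs, rank, kref, fr, aa = best
        if ev >= e_recruit:
            continue
        score, (qs, qe), (rs, re_), _pair = smith_waterman(
            aa, refs[kref].seq, scheme
        )
        aa_trim = _mask_aa(aa[qs:qe])
        if len(aa_trim) < min_aa:
            continue
        off = abs(fr) - 1
        if fr > 0:
            span = (off + 3 * qs, off + 3 * qe)
        else:
            L = len(read.seq)
            span = (L - (off + 3 * qe), L - (off + 3 * qs))
        out.append(
            RecruitedRead(
                read_id=read.id,
                mate=mate,
                frame=fr,
                aa_seq=aa_trim,
                dna_span=span,
                score=score,
                evalue=ev,
                best_ref=refs[kref].id,
                ref_span=(rs, re_),
            )
        )
    return out
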