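"""Protein-to-genome homology search and intron-aware spliced alignment.

This module plays the role that a translated BLAST search plus a spliced
gene-prediction aligner play in classical retrocopy pipelines, scaled to
in-memory genomes:

* :func:`search_protein_vs_genome` seeds exact 4-aa word matches against all
  six translation frames and extends them gaplessly (BLOSUM62, X-drop) into
  HSPs, gated on identity, aligned length and raw score.
* :func:`chain_hsps` groups collinear same-strand HSPs within a maximum
  intron span into candidate loci.
* :func:`spliced_align` parses a genomic locus against a query protein with
  a dynamic program whose states cover codon matches, amino-acid/codon gaps,
  1-2 bp frameshift slips, and GT..AG introns, yielding the exon structure,
  frameshift and in-frame-stop positions needed to classify retrocopies.

Introns are modelled at codon boundaries (phase 0); phase-1/2 introns in
real annotations surface as one-residue fuzz around the boundary, which the
downstream ±5 aa intron-position tolerance absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import GenomeAssembly, reverse_complement

# ---------------------------------------------------------------------------
# scoring tables


_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_BLOSUM.alphabet)  # includes X and *
_AA_INDEX = np.full(256, _ALPHA.index("X"), dtype=np.int16)
for _i, _c in enumerate(_ALPHA):
    _AA_INDEX[ord(_c)] = _i
_NALPHA = len(_ALPHA)
_SM = np.asarray(_BLOSUM, dtype=np.float32)

_BASE_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

# codon integer code (b0*16+b1*4+b2, bases in ACGT order) -> aa index;
# 64 = codon containing N, which scores 0 against anything
from Bio.Seq import Seq as _Seq

_CODON_AA = np.empty(65, dtype=np.int16)
for _ci in range(64):
    _codon = "ACGT"[_ci // 16] + "ACGT"[(_ci // 4) % 4] + "ACGT"[_ci % 4]
    _CODON_AA[_ci] = _AA_INDEX[ord(str(_Seq(_codon).translate()))]
_CODON_AA[64] = -1

_STOP_AA = _ALPHA.index("*")


def _encode_protein(protein: str) -> np.ndarray:
    return _AA_INDEX[np.frombuffer(protein.upper().encode(), dtype=np.uint8)]


def _codon_codes(dna: str) -> np.ndarray:
    """aa index of the codon starting at each dna position (-1 where the
    codon contains N; _STOP_AA for stops); length len(dna) (tail = -1)."""
    b = _BASE_CODE[np.frombuffer(dna.upper().encode(), dtype=np.uint8)]
    n = len(dna)
    out = np.full(n, -1, dtype=np.int16)
    if n < 3:
        return out
    c0, c1, c2 = b[:-2], b[1:-1], b[2:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0)
    code = np.where(valid, c0 * 16 + c1 * 4 + c2, 64)
    out[: n - 2] = _CODON_AA[code]
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SearchParams:
    """Tunables of the homology search and spliced aligner."""

    word_size: int = 4
    min_aa: int = 50  # minimum protein length searched / HSP length kept
    min_identity: float = 0.5
    min_score: float = 50.0
    x_drop: float = 12.0
    two_hit: bool = True  # require two word hits on a diagonal before extending
    seed_window: int = 60  # aa window for the two-hit rule
    max_intron: int = 50_000
    min_intron: int = 30
    frameshift_penalty: float = -20.0
    intron_penalty: float = -25.0
    gap_aa: float = -10.0  # unaligned protein residue
    gap_codon: float = -10.0  # skipped codon in the DNA
    min_structure_score: float = 35.0
    flank: int = 1000


@dataclass
class Hsp:
    """A gapless high-scoring segment pair in one translation frame."""

    protein_id: str
    chrom: str
    strand: str
    frame: int
    prot_start: int  # aa, half-open
    prot_end: int
    g_start: int  # bp, half-open, forward-strand genomic coordinates
    g_end: int
    score: float
    identity: float

    @property
    def aa_length(self) -> int:
        return self.prot_end - self.prot_start


@dataclass
class CandidateLocus:
    """A chained group of collinear HSPs from one protein."""

    protein_id: str
    chrom: str
    strand: str
    g_start: int
    g_end: int
    hsps: list[Hsp]

    @property
    def score(self) -> float:
        return sum(h.score for h in self.hsps)


@dataclass
class ExonSegment:
    g_start: int  # local coordinates within the aligned DNA string
    g_end: int
    prot_start: int
    prot_end: int


@dataclass
class SplicedStructure:
    """Optimal parse of a protein against a genomic locus."""

    score: float
    exons: list[ExonSegment]
    frameshift_positions: list[int]  # protein coordinates (0-based)
    stop_positions: list[int]
    codon_matches: list[tuple[int, int]]  # (protein idx, dna codon start)
    aligned_aa: int
    matched_aa: int
    protein_length: int
    accepted: bool = True

    @property
    def intron_count(self) -> int:
        return max(0, len(self.exons) - 1)

    @property
    def coverage(self) -> float:
        return self.aligned_aa / self.protein_length if self.protein_length else 0.0

    @property
    def identity(self) -> float:
        return self.matched_aa / len(self.codon_matches) if self.codon_matches else 0.0

    def intron_positions_aa(self) -> list[int]:
        """Protein coordinate at which each intron interrupts the parse."""
        return [seg.prot_end for seg in self.exons[:-1]]


REJECTED = SplicedStructure(
    score=0.0,
    exons=[],
    frameshift_positions=[],
    stop_positions=[],
    codon_matches=[],
    aligned_aa=0,
    matched_aa=0,
    protein_length=0,
    accepted=False,
)


# ---------------------------------------------------------------------------
# six-frame word index


class GenomeIndex:
    """Sorted-hash index of 4-aa words over all six translation frames."""

    def __init__(self, genome: GenomeAssembly, word_size: int = 4):
        if word_size != 4:
            raise ValueError("word_size 4 is the supported seed size")
        self.genome = genome
        self.word_size = word_size
        self.frames: list[tuple[str, str, int, np.ndarray, int]] = []
        # per frame: sorted word-hash array + argsort positions
        self._hashes: list[np.ndarray] = []
        self._positions: list[np.ndarray] = []
        for chrom, seq in genome.sequences.items():
            for strand in "+-":
                s = seq if strand == "+" else reverse_complement(seq)
                for frame in range(3):
                    codes = _codon_codes(s)[frame::3]
                    if codes.size < word_size:
                        continue
                    self.frames.append((chrom, strand, frame, codes, len(s)))
                    h = self._word_hashes(codes)
                    order = np.argsort(h, kind="stable")
                    self._hashes.append(h[order])
                    self._positions.append(order.astype(np.int64))

    @staticmethod
    def _word_hashes(codes: np.ndarray) -> np.ndarray:
        c = codes.astype(np.int64)
        # ambiguous (-1) words never match queries
        k = len(c)
        h = (
            c[: k - 3] * _NALPHA**3
            + c[1 : k - 2] * _NALPHA**2
            + c[2 : k - 1] * _NALPHA
            + c[3:]
        )
        h[(c[: k - 3] < 0) | (c[1 : k - 2] < 0) | (c[2 : k - 1] < 0) | (c[3:] < 0)] = -1
        return h

    def lookup_many(
        self, word_hashes: np.ndarray, frame_idx: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised lookup: (query positions with hits, lo, hi) such that
        positions[lo[k]:hi[k]] are the frame positions of query word k."""
        h = self._hashes[frame_idx]
        lo = np.searchsorted(h, word_hashes, side="left")
        hi = np.searchsorted(h, word_hashes, side="right")
        hits = np.flatnonzero(hi > lo)
        return hits, lo, hi


def _extend_seed(
    pvec: np.ndarray,
    tvec: np.ndarray,
    q0: int,
    q1: int,
    t0: int,
    x_drop: float,
) -> tuple[int, int, float, float]:
    """Gapless X-drop extension of a seed run; returns (qstart, qend, score,
    identity) in query coordinates (target start = qstart + diag)."""
    diag = t0 - q0
    scores = np.where(
        (tvec[q0 + diag : q1 + diag] >= 0),
        _SM[pvec[q0:q1], np.maximum(tvec[q0 + diag : q1 + diag], 0)],
        0.0,
    )
    best = total = float(scores.sum())
    # extend right
    qe, cur, best_qe = q1, total, q1
    j = q1
    qmax = min(len(pvec), len(tvec) - diag)
    while j < qmax:
        t = tvec[j + diag]
        cur += _SM[pvec[j], t] if t >= 0 else 0.0
        j += 1
        if cur > best:
            best, best_qe = cur, j
        if cur < best - x_drop:
            break
    # extend left
    cur, best_qs = best, q0
    j = q0
    qmin = max(0, -diag)
    while j > qmin:
        j -= 1
        t = tvec[j + diag]
        cur += _SM[pvec[j], t] if t >= 0 else 0.0
        if cur > best:
            best, best_qs = cur, j
        if cur < best - x_drop:
            break
    ident_run = [
        1 if (tvec[q + diag] >= 0 and pvec[q] == tvec[q + diag]) else 0
        for q in range(best_qs, best_qe)
    ]
    identity = sum(ident_run) / max(1, len(ident_run))
    return best_qs, best_qe, best, identity


def search_protein_vs_genome(
    protein_id: str,
    protein: str,
    index: GenomeIndex,
    params: SearchParams | None = None,
) -> list[Hsp]:
    """Find HSPs of a protein against all six genome frames.

    Seeds are exact 4-aa word matches, extended gaplessly with BLOSUM62 and
    an X-drop rule; HSPs pass when identity > ``min_identity``, aligned
    length ≥ ``min_aa`` and score ≥ ``min_score``. Overlapping same-frame
    HSPs are merged (best-scoring kept).
    """
    params = params or SearchParams()
    if len(protein) < params.min_aa:
        return []
    pvec = _encode_protein(protein)
    k = params.word_size
    q = pvec.astype(np.int64)
    nq = len(q) - k + 1
    if nq <= 0:
        return []
    qh = (
        q[:nq] * _NALPHA**3 + q[1 : nq + 1] * _NALPHA**2 + q[2 : nq + 2] * _NALPHA + q[3 : nq + 3]
    )

    hsps: list[Hsp] = []
    for fi, (chrom, strand, frame, codes, slen) in enumerate(index.frames):
        # seed positions per diagonal
        diag_hits: dict[int, list[tuple[int, int]]] = {}
        hit_qps, los, his = index.lookup_many(qh, fi)
        positions = index._positions[fi]
        for qp in hit_qps:
            for tp in positions[los[qp] : his[qp]]:
                diag_hits.setdefault(int(tp) - qp, []).append((int(qp), int(tp)))
        tvec = codes
        for diag, hits in diag_hits.items():
            hits.sort()
            if params.two_hit and len(hits) < 2:
                continue
            # cluster hits along the diagonal
            clusters: list[list[tuple[int, int]]] = [[hits[0]]]
            for h in hits[1:]:
                if h[0] - clusters[-1][-1][0] <= params.seed_window:
                    clusters[-1].append(h)
                else:
                    clusters.append([h])
            for cl in clusters:
                if params.two_hit and len(cl) < 2:
                    continue
                q0 = cl[0][0]
                q1 = cl[-1][0] + k
                qs, qe, score, ident = _extend_seed(
                    pvec, tvec, q0, q1, q0 + diag, params.x_drop
                )
                if (
                    qe - qs < params.min_aa
                    or ident <= params.min_identity
                    or score < params.min_score
                ):
                    continue
                ts, te = qs + diag, qe + diag
                # frame aa coordinates -> forward genomic bp
                if strand == "+":
                    g0 = frame + 3 * ts
                    g1 = frame + 3 * te
                else:
                    g1 = slen - (frame + 3 * ts)
                    g0 = slen - (frame + 3 * te)
                hsps.append(
                    Hsp(
                        protein_id=protein_id,
                        chrom=chrom,
                        strand=strand,
                        frame=frame,
                        prot_start=qs,
                        prot_end=qe,
                        g_start=g0,
                        g_end=g1,
                        score=score,
                        identity=ident,
                    )
                )
    return _merge_overlapping(hsps)


def _merge_overlapping(hsps: list[Hsp]) -> list[Hsp]:
    """Drop same-frame HSPs whose genomic span overlaps a higher-scoring one."""
    kept: list[Hsp] = []
    for h in sorted(hsps, key=lambda h: -h.score):
        clash = any(
            k.chrom == h.chrom
            and k.strand == h.strand
            and k.frame == h.frame
            and k.g_start < h.g_end
            and h.g_start < k.g_end
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.strand, h.g_start))
    return kept


def chain_hsps(hsps: list[Hsp], max_intron: int = 50_000) -> list[CandidateLocus]:
    """Chain same-chromosome, same-strand, collinear HSPs into loci.

    Two HSPs join one chain when their genomic gap is within ``max_intron``
    and their protein order matches their genomic order (reversed on the
    minus strand). The locus span is the union envelope of its HSPs.
    """
    loci: list[CandidateLocus] = []
    by_key: dict[tuple[str, str, str], list[Hsp]] = {}
    for h in hsps:
        by_key.setdefault((h.protein_id, h.chrom, h.strand), []).append(h)
    for (pid, chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.g_start)
        chains: list[list[Hsp]] = []
        for h in group:
            attached = False
            for chain in chains:
                last = chain[-1]
                gap = h.g_start - last.g_end
                if gap > max_intron:
                    continue
                if strand == "+":
                    collinear = h.prot_start >= last.prot_start and h.prot_end >= last.prot_end
                else:
                    collinear = h.prot_start <= last.prot_start and h.prot_end <= last.prot_end
                if collinear:
                    chain.append(h)
                    attached = True
                    break
            if not attached:
                chains.append([h])
        for chain in chains:
            loci.append(
                CandidateLocus(
                    protein_id=pid,
                    chrom=chrom,
                    strand=strand,
                    g_start=min(h.g_start for h in chain),
                    g_end=max(h.g_end for h in chain),
                    hsps=chain,
                )
            )
    loci.sort(key=lambda c: (c.chrom, c.g_start, c.protein_id))
    return loci


# ---------------------------------------------------------------------------
# spliced alignment DP


_PTR_NONE = 0
_PTR_CODON = 1
_PTR_FS = {1: 2, 2: 3, 4: 4, 5: 5}  # bases consumed -> code
_FS_BASES = {2: 1, 3: 2, 4: 4, 5: 5}
_PTR_PGAP = 6
_PTR_DGAP = 7
_PTR_INTRON = 8


def spliced_align(
    protein: str, dna: str, params: SearchParams | None = None
) -> SplicedStructure:
    """Best local parse of ``protein`` against ``dna`` (see module docs).

    The dynamic program scores codon matches with BLOSUM62 (stop codons use
    the matrix's ``*`` column and are recorded as in-frame stops), charges
    ``frameshift_penalty`` for 1-2 bp slips (codons of 1, 2, 4 or 5 bases),
    linear gap costs for unaligned residues/codons, and a flat
    ``intron_penalty`` for introns entered at ``GT`` and left at ``AG`` with
    length ≥ ``min_intron``. Parses scoring ≤ ``min_structure_score`` are
    rejected (sentinel with ``accepted=False``).
    """
    params = params or SearchParams()
    P, D = len(protein), len(dna)
    if P == 0 or D < 3:
        return REJECTED
    pvec = _encode_protein(protein)
    codes = _codon_codes(dna)  # aa index of codon starting at j

    sub_by_prot = _SM[pvec]  # P x nalpha
    # score of aligning residue i-1 with codon starting at j: col[j][i-1]
    M = np.full((P + 1, D + 1), 0.0, dtype=np.float32)
    ptr = np.zeros((P + 1, D + 1), dtype=np.uint8)
    intron_from = None

    dna_b = dna.upper().encode()
    is_gt = np.zeros(D + 1, dtype=bool)
    is_ag = np.zeros(D + 1, dtype=bool)
    for j in range(D - 1):
        if dna_b[j : j + 2] == b"GT":
            is_gt[j] = True
    for j in range(2, D + 1):
        if dna_b[j - 2 : j] == b"AG":
            is_ag[j] = True

    neg_inf = np.float32(-1e9)
    dbest = np.full(P + 1, neg_inf, dtype=np.float32)
    dbest_arg = np.zeros(P + 1, dtype=np.int64)
    fs_pen = np.float32(params.frameshift_penalty)
    ii = np.arange(P + 1)

    for j in range(1, D + 1):
        # admit donors at j' = j - min_intron
        jd = j - params.min_intron
        if jd >= 0 and is_gt[jd]:
            col = M[:, jd]
            better = col > dbest
            if better.any():
                dbest = np.where(better, col, dbest)
                dbest_arg = np.where(better, jd, dbest_arg)

        best = np.zeros(P + 1, dtype=np.float32)  # local floor
        code = np.zeros(P + 1, dtype=np.uint8)

        if j >= 3:
            aa = codes[j - 3]
            if aa >= 0:
                colscore = sub_by_prot[:, aa]
            else:
                colscore = np.zeros(P, dtype=np.float32)  # N codon: 0 vs anything
            cand = M[:-1, j - 3] + colscore
            take = cand > best[1:]
            best[1:] = np.where(take, cand, best[1:])
            code[1:] = np.where(take, np.uint8(_PTR_CODON), code[1:])

            cand = M[:, j - 3] + np.float32(params.gap_codon)
            take = cand > best
            best = np.where(take, cand, best)
            code = np.where(take, np.uint8(_PTR_DGAP), code)

        for nb, pcode in _PTR_FS.items():
            if j >= nb:
                cand = M[:-1, j - nb] + fs_pen
                take = cand > best[1:]
                best[1:] = np.where(take, cand, best[1:])
                code[1:] = np.where(take, np.uint8(pcode), code[1:])

        if is_ag[j]:
            cand = dbest + np.float32(params.intron_penalty)
            take = cand > best
            if take.any():
                best = np.where(take, cand, best)
                code = np.where(take, np.uint8(_PTR_INTRON), code)
                if intron_from is None:
                    intron_from = np.zeros((P + 1, D + 1), dtype=np.int32)
                intron_from[take, j] = dbest_arg[take]

        # vertical: unaligned protein residues (i-1, j) -> (i, j)
        g = np.float32(params.gap_aa)
        a = best - ii * g
        acc = np.maximum.accumulate(a[:-1])
        vert = acc + ii[1:] * g
        take = vert > best[1:]
        if take.any():
            best[1:] = np.where(take, vert, best[1:])
            code[1:] = np.where(take, np.uint8(_PTR_PGAP), code[1:])

        M[:, j] = best
        ptr[:, j] = code

    flat = int(np.argmax(M))
    bi, bj = divmod(flat, D + 1)
    best_score = float(M[bi, bj])
    if best_score <= params.min_structure_score:
        return REJECTED

    # traceback
    i, j = bi, bj
    codon_matches: list[tuple[int, int]] = []
    stops: list[int] = []
    fs: list[int] = []
    intron_bounds: list[tuple[int, int]] = []
    min_i, max_i = i, i
    min_j, max_j = j, j
    matched = 0
    while i > 0 or j > 0:
        if M[i, j] == 0 and ptr[i, j] == _PTR_NONE:
            break
        code = int(ptr[i, j])
        if code == _PTR_NONE:
            break
        if code == _PTR_CODON:
            aa = codes[j - 3]
            codon_matches.append((i - 1, j - 3))
            if aa == _STOP_AA:
                stops.append(i - 1)
            elif aa >= 0 and aa == pvec[i - 1]:
                matched += 1
            i, j = i - 1, j - 3
        elif code in (2, 3, 4, 5):
            fs.append(i - 1)
            i, j = i - 1, j - _FS_BASES[code]
        elif code == _PTR_PGAP:
            i -= 1
        elif code == _PTR_DGAP:
            j -= 3
        elif code == _PTR_INTRON:
            donor = int(intron_from[i, j])
            intron_bounds.append((donor, j))
            j = donor
        min_i, max_i = min(min_i, i), max(max_i, i)
        min_j, max_j = min(min_j, j), max(max_j, j)

    codon_matches.reverse()
    stops.sort()
    fs.sort()
    intron_bounds.sort()

    # exon segments between intron boundaries
    exons: list[ExonSegment] = []
    seg_start_j, seg_start_i = min_j, min_i
    for donor, acceptor in intron_bounds:
        prot_at = _prot_pos_at(codon_matches, fs, donor)
        exons.append(ExonSegment(seg_start_j, donor, seg_start_i, prot_at))
        seg_start_j, seg_start_i = acceptor, prot_at
    exons.append(ExonSegment(seg_start_j, max_j, seg_start_i, max_i))

    return SplicedStructure(
        score=best_score,
        exons=exons,
        frameshift_positions=fs,
        stop_positions=stops,
        codon_matches=codon_matches,
        aligned_aa=max_i - min_i,
        matched_aa=matched,
        protein_length=P,
        accepted=True,
    )


def _prot_pos_at(
    codon_matches: list[tuple[int, int]], fs: list[int], dna_pos: int
) -> int:
    """Protein coordinate reached at or before a DNA position."""
    best = 0
    for i, j in codon_matches:
        if j < dna_pos:
            best = max(best, i + 1)
    return best
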