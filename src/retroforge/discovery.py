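"""Retrocopy catalogue construction.

Turns spliced structures into a catalogue of retrocopies: single-exon
candidate calling with self-hit exclusion, best-parent assignment against
the full proteome, an intron-retention check that discards DNA-level
duplicates, intact/pseudogene classification, chimeric flagging, and
catalogue summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from intervaltree import IntervalTree

from .homology import (
    GenomeIndex,
    SearchParams,
    SplicedStructure,
    chain_hsps,
    search_protein_vs_genome,
    spliced_align,
)
from .io_formats import GeneModel, GenomeAssembly, ProteinRecord, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryParams:
    """Gates of the retrocopy caller."""

    search: SearchParams = field(default_factory=SearchParams)
    parent_min_identity: float = 0.5
    parent_min_overlap: float = 0.5
    parent_min_aa: int = 50
    intron_match_tolerance_aa: int = 5
    recheck_flank: int = 2000
    dedup_reciprocal_overlap: float = 0.5
    stop_grace_fraction: float = 0.0  # ignore stops in the final fraction of the parent


@dataclass
class RetrocopyRecord:
    """One called retrocopy locus."""

    retro_id: str
    chrom: str
    strand: str
    start: int
    end: int
    parent_gene: str
    parent_protein: str
    cls: str  # "intact" | "pseudogene"
    chimeric: bool
    overlaps_annotation: bool
    identity: float
    coverage: float
    n_frameshifts: int
    n_stops: int
    score: float
    codon_pairs: list[tuple[str, str]] = field(default_factory=list, repr=False)


@dataclass
class CatalogueSummary:
    total: int
    intact: int
    pseudogene: int
    chimeric: int
    n_parents: int
    per_parent: dict[str, int]
    novel_total: int
    novel_intact: int

    @property
    def intact_fraction(self) -> float:
        return self.intact / self.total if self.total else 0.0

    @property
    def retrocopies_per_parent(self) -> float:
        return self.total / self.n_parents if self.n_parents else 0.0

    @property
    def single_retrocopy_parent_fraction(self) -> float:
        if not self.n_parents:
            return 0.0
        ones = sum(1 for v in self.per_parent.values() if v == 1)
        return ones / self.n_parents

    def top_parents(self, n: int = 20) -> list[tuple[str, int]]:
        return sorted(self.per_parent.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


@dataclass
class Candidate:
    """Internal: an intronless locus called from one query protein."""

    chrom: str
    strand: str
    start: int
    end: int
    query_protein: str
    structure: SplicedStructure
    dna: str  # strand-oriented window sequence
    win_start: int
    win_end: int

    @property
    def score(self) -> float:
        return self.structure.score


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _local_to_genomic(strand: str, win_start: int, win_end: int, lo: int, hi: int) -> tuple[int, int]:
    if strand == "+":
        return win_start + lo, win_start + hi
    return win_end - hi, win_end - lo


def _structure_translation(structure: SplicedStructure, dna: str) -> str:
    """Conceptual translation of the aligned codons of a candidate."""
    from .io_formats import translate

    out = []
    for _, j in structure.codon_matches:
        codon = dna[j : j + 3]
        out.append(translate(codon + "A" * ((3 - len(codon) % 3) % 3))[:1] or "X")
    return "".join(out)


def find_structures(
    genome: GenomeAssembly,
    proteins: list[ProteinRecord],
    params: DiscoveryParams | None = None,
    index: GenomeIndex | None = None,
) -> list[Candidate]:
    """Search every protein against the genome and parse each chained locus.

    Returns all accepted parses (any intron count) as :class:`Candidate`
    shells; candidate calling proper happens in :func:`call_candidates`.
    """
    params = params or DiscoveryParams()
    index = index or GenomeIndex(genome)
    out: list[Candidate] = []
    for prot in proteins:
        hsps = search_protein_vs_genome(prot.protein_id, prot.sequence, index, params.search)
        for locus in chain_hsps(hsps, params.search.max_intron):
            clen = genome.lengths[locus.chrom]
            ws = max(0, int(locus.g_start) - params.search.flank)
            we = min(clen, int(locus.g_end) + params.search.flank)
            dna = genome.fetch(locus.chrom, ws, we)
            if locus.strand == "-":
                dna = reverse_complement(dna)
            st = spliced_align(prot.sequence, dna, params.search)
            if not st.accepted or not st.exons:
                continue
            lo = min(seg.g_start for seg in st.exons)
            hi = max(seg.g_end for seg in st.exons)
            g0, g1 = _local_to_genomic(locus.strand, ws, we, lo, hi)
            out.append(
                Candidate(
                    chrom=locus.chrom,
                    strand=locus.strand,
                    start=g0,
                    end=g1,
                    query_protein=prot.protein_id,
                    structure=st,
                    dna=dna,
                    win_start=ws,
                    win_end=we,
                )
            )
    return out


def call_candidates(
    structures: list[Candidate],
    models: list[GeneModel],
    params: DiscoveryParams | None = None,
) -> list[Candidate]:
    """Keep intronless parses that do not overlap the query's own gene."""
    params = params or DiscoveryParams()
    gene_of_protein = {m.protein_id: m for m in models}
    kept = []
    for c in structures:
        if c.structure.intron_count != 0:
            continue
        own = gene_of_protein.get(c.query_protein)
        if own is not None and own.chrom == c.chrom and own.start < c.end and c.start < own.end:
            continue
        kept.append(c)
    return _dedup(kept, params.dedup_reciprocal_overlap)


def _dedup(cands: list[Candidate], reciprocal: float) -> list[Candidate]:
    """Collapse candidates covering the same locus (reciprocal overlap),
    keeping the higher structure score (then lexicographic query id)."""
    kept: list[Candidate] = []
    for c in sorted(cands, key=lambda c: (-c.score, c.query_protein)):
        dup = False
        for k in kept:
            if k.chrom != c.chrom:
                continue
            ov = min(k.end, c.end) - max(k.start, c.start)
            if ov <= 0:
                continue
            if ov > reciprocal * (k.end - k.start) and ov > reciprocal * (c.end - c.start):
                dup = True
                break
        if not dup:
            kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.start, c.query_protein))
    return kept


def assign_parent(
    candidate: Candidate,
    proteins: list[ProteinRecord],
    models: list[GeneModel],
    params: DiscoveryParams | None = None,
    aligner: PairwiseAligner | None = None,
) -> tuple[ProteinRecord, float, float] | None:
    """Best-scoring parent protein for a candidate's conceptual translation.

    The translation is aligned (Smith–Waterman, BLOSUM62) against every
    protein; the best scorer wins when identity > 0.5, overlap > 0.5 and the
    alignment spans ≥ 50 aa; ties break by higher identity, then gene id.
    Returns None (candidate discarded) when the winner's gene is single-exon
    or no protein passes the gates.
    """
    params = params or DiscoveryParams()
    aligner = aligner or _protein_aligner()
    query = _structure_translation(candidate.structure, candidate.dna)
    if not query:
        return None
    gene_of_protein = {m.protein_id: m for m in models}
    scored: list[tuple[float, float, str, ProteinRecord, float]] = []
    for prot in proteins:
        try:
            aln = aligner.align(query.replace("*", "X"), prot.sequence)[0]
        except (IndexError, ValueError):
            continue
        blocks = aln.aligned
        alen = int(sum(b1 - b0 for b0, b1 in blocks[0]))
        if alen < params.parent_min_aa:
            continue
        matches = 0
        for (q0, q1), (t0, t1) in zip(*blocks):
            for k in range(q1 - q0):
                if query[q0 + k] == prot.sequence[t0 + k]:
                    matches += 1
        identity = matches / alen if alen else 0.0
        overlap = alen / len(prot.sequence)
        if identity <= params.parent_min_identity or overlap <= params.parent_min_overlap:
            continue
        scored.append((float(aln.score), identity, prot.gene_id, prot, overlap))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best = scored[0]
    if len(scored) > 1 and scored[1][0] == best[0] and scored[1][1] == best[1]:
        logger.info(
            "parent tie for candidate %s:%d-%d broken lexicographically (%s over %s)",
            candidate.chrom,
            candidate.start,
            candidate.end,
            best[2],
            scored[1][2],
        )
    model = gene_of_protein.get(best[3].protein_id)
    if model is None or model.n_exons < 2:
        logger.info(
            "candidate %s:%d-%d discarded: best hit %s is single-exon",
            candidate.chrom,
            candidate.start,
            candidate.end,
            best[2],
        )
        return None
    return best[3], best[1], best[4]


def check_intron_loss(
    candidate: Candidate,
    parent_model: GeneModel,
    parent_protein: ProteinRecord,
    genome: GenomeAssembly,
    params: DiscoveryParams | None = None,
) -> tuple[bool, SplicedStructure]:
    """Re-parse the candidate locus (±2 kb) with the parent protein.

    Returns (keep, structure): the candidate is discarded when the best
    parse contains an intron whose protein position falls within ±5 aa of a
    parental intron position — the signature of a DNA-level duplicate.
    """
    params = params or DiscoveryParams()
    clen = genome.lengths[candidate.chrom]
    ws = max(0, candidate.start - params.recheck_flank)
    we = min(clen, candidate.end + params.recheck_flank)
    dna = genome.fetch(candidate.chrom, ws, we)
    if candidate.strand == "-":
        dna = reverse_complement(dna)
    st = spliced_align(parent_protein.sequence, dna, params.search)
    if not st.accepted:
        return False, st
    parental = parent_model.intron_positions_aa()
    tol = params.intron_match_tolerance_aa
    for pos in st.intron_positions_aa():
        if any(abs(pos - p) <= tol for p in parental):
            return False, st
    # refresh the candidate with the parent-guided parse
    lo = min(seg.g_start for seg in st.exons)
    hi = max(seg.g_end for seg in st.exons)
    g0, g1 = _local_to_genomic(candidate.strand, ws, we, lo, hi)
    candidate.start, candidate.end = g0, g1
    candidate.dna = dna
    candidate.win_start, candidate.win_end = ws, we
    return True, st


def classify(structure: SplicedStructure, grace_fraction: float = 0.0) -> str:
    """intact iff the parse shows no frameshift and no premature stop.

    A stop is premature when it falls before the column aligned to the
    parent's final codon; with ``grace_fraction`` > 0 stops inside the final
    fraction of the parent protein are forgiven.
    """
    limit = structure.protein_length * (1.0 - grace_fraction)
    stops = [s for s in structure.stop_positions if s < limit]
    if structure.frameshift_positions or stops:
        return "pseudogene"
    return "intact"


def _gene_trees(models: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in models:
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end, m)
    return trees


def flag_chimeric(
    chrom: str,
    strand: str,
    start: int,
    end: int,
    cls: str,
    parent_gene: str,
    trees: dict[str, IntervalTree],
) -> bool:
    """True iff an intact retrocopy lies strictly inside a same-strand host
    gene (different from the parent) that keeps ≥ 1 CDS exon outside the
    retrocopy span."""
    if cls != "intact":
        return False
    for iv in trees.get(chrom, IntervalTree()).overlap(start, end):
        host: GeneModel = iv.data
        if host.gene_id == parent_gene or host.strand != strand:
            continue
        if host.start <= start and end <= host.end:
            if any(b <= start or a >= end for a, b in host.exons):
                return True
    return False


def _overlaps_any_gene(chrom: str, start: int, end: int, trees: dict[str, IntervalTree]) -> bool:
    return bool(trees.get(chrom, IntervalTree()).overlap(start, end))


def discover(
    genome: GenomeAssembly,
    models: list[GeneModel],
    proteins: list[ProteinRecord],
    params: DiscoveryParams | None = None,
    index: GenomeIndex | None = None,
) -> list[RetrocopyRecord]:
    """Run the full retrocopy-calling chain and return the catalogue,
    stably sorted by (chromosome, start, retro id)."""
    params = params or DiscoveryParams()
    structures = find_structures(genome, proteins, params, index)
    candidates = call_candidates(structures, models, params)
    aligner = _protein_aligner()
    protein_cds: dict[str, str] = {}
    model_of_gene = {m.gene_id: m for m in models}
    trees = _gene_trees(models)

    records: list[RetrocopyRecord] = []
    for cand in candidates:
        assigned = assign_parent(cand, proteins, models, params, aligner)
        if assigned is None:
            continue
        parent, _, _ = assigned
        parent_model = model_of_gene[parent.gene_id]
        keep, st = check_intron_loss(cand, parent_model, parent, genome, params)
        if not keep or st.intron_count != 0:
            continue
        cls = classify(st, params.stop_grace_fraction)
        chimeric = flag_chimeric(
            cand.chrom, cand.strand, cand.start, cand.end, cls, parent.gene_id, trees
        )
        # codon pairs parent CDS vs retro locus, from the parent-guided parse
        if parent.protein_id not in protein_cds:
            from .io_formats import extract_cds

            protein_cds[parent.protein_id] = extract_cds(parent_model, genome)
        pcds = protein_cds[parent.protein_id]
        pairs = []
        for i, j in st.codon_matches:
            a = pcds[i * 3 : i * 3 + 3]
            b = cand.dna[j : j + 3]
            from .kaks import _is_clean

            if _is_clean(a) and _is_clean(b):
                pairs.append((a, b))
        records.append(
            RetrocopyRecord(
                retro_id="",
                chrom=cand.chrom,
                strand=cand.strand,
                start=cand.start,
                end=cand.end,
                parent_gene=parent.gene_id,
                parent_protein=parent.protein_id,
                cls=cls,
                chimeric=chimeric,
                overlaps_annotation=_overlaps_any_gene(cand.chrom, cand.start, cand.end, trees),
                identity=st.identity,
                coverage=st.coverage,
                n_frameshifts=len(st.frameshift_positions),
                n_stops=len(st.stop_positions),
                score=st.score,
                codon_pairs=pairs,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.parent_gene))
    records = _dedup_records(records, params.dedup_reciprocal_overlap)
    for i, r in enumerate(records):
        r.retro_id = f"retro{i + 1:04d}"
    return records


def _dedup_records(records: list[RetrocopyRecord], reciprocal: float) -> list[RetrocopyRecord]:
    kept: list[RetrocopyRecord] = []
    for r in sorted(records, key=lambda r: (-r.score, r.chrom, r.start)):
        dup = False
        for k in kept:
            if k.chrom != r.chrom:
                continue
            ov = min(k.end, r.end) - max(k.start, r.start)
            if ov <= 0:
                continue
            if ov > reciprocal * (k.end - k.start) and ov > reciprocal * (r.end - r.start):
                dup = True
                break
        if not dup:
            kept.append(r)
    kept.sort(key=lambda r: (r.chrom, r.start, r.parent_gene))
    return kept


def summarize(records: list[RetrocopyRecord]) -> CatalogueSummary:
    """Catalogue totals, per-parent counts and novel (annotation-free) counts."""
    per_parent: dict[str, int] = {}
    for r in records:
        per_parent[r.parent_gene] = per_parent.get(r.parent_gene, 0) + 1
    return CatalogueSummary(
        total=len(records),
        intact=sum(r.cls == "intact" for r in records),
        pseudogene=sum(r.cls == "pseudogene" for r in records),
        chimeric=sum(r.chimeric for r in records),
        n_parents=len(per_parent),
        per_parent=per_parent,
        novel_total=sum(not r.overlaps_annotation for r in records),
        novel_intact=sum((not r.overlaps_annotation) and r.cls == "intact" for r in records),
    )


def catalogue_frame(records: list[RetrocopyRecord]) -> pd.DataFrame:
    cols = [
        "retro_id",
        "chrom",
        "strand",
        "start",
        "end",
        "parent_gene",
        "parent_protein",
        "cls",
        "chimeric",
        "overlaps_annotation",
        "identity",
        "coverage",
        "n_frameshifts",
        "n_stops",
        "score",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
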