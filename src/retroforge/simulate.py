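"""Synthetic genome / annotation / retrotransposition / EST simulator.

Generates a multi-chromosome genome carrying multi-exon protein-coding genes
with canonical GT..AG introns, injects retrotransposition events (intronless
copies of spliced CDSs with configurable divergence, frameshifts, premature
stops, chimeric intronic insertions, poly-A tails and target-site
duplications), samples error-bearing EST reads from expressed loci, and
records every event in a ground-truth table for recovery testing.

All randomness flows from a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeAssembly,
    GeneModel,
    ProteinRecord,
    reverse_complement,
    translate,
    write_fasta,
    write_gtf_cds,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults emulate a desk-scale genome: ~2 Mb over five autosomes plus an
    X chromosome, 40 multi-exon genes, 50 retrotransposition events whose
    divergence targets the Ks range where retrotransposition activity
    concentrates in carnivore genomes (Ks ~ 0.02-0.06), and ESTs at the
    read length and error rate typical of single-pass cDNA sequencing.
    """

    seed: int = 0
    n_chromosomes: int = 6  # last one is named X
    chromosome_length: int = 330_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 8)  # uniform inclusive
    exon_length: tuple[int, int] = (90, 300)  # bp, uniform inclusive
    intron_length: tuple[int, int] = (80, 400)
    intergenic_gc: float = 0.41
    n_retro_events: int = 50
    substitution_rate: float = 0.04  # per site, uniform across sites
    kappa: float = 1.0  # transition/transversion bias (1 = unbiased)
    frameshift_prob: float = 0.3
    premature_stop_prob: float = 0.3
    chimeric_prob: float = 0.1
    polya_length: int = 30
    tsd_length: int = 10
    n_dna_duplicates: int = 0
    n_ests: int = 300
    est_length: int = 400
    est_error_rate: float = 0.01
    expressed_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "frameshift_prob",
            "premature_stop_prob",
            "chimeric_prob",
            "est_error_rate",
            "expressed_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.chromosome_length <= 0 or self.n_chromosomes < 1:
            raise ValueError("chromosome dimensions must be positive")

    def chromosome_names(self) -> list[str]:
        names = [f"chr{i + 1}" for i in range(self.n_chromosomes - 1)]
        names.append("chrX")
        return names


@dataclass
class TruthEvent:
    """Ground truth for one simulated insertion event."""

    event_id: str
    kind: str  # "retro" | "dna_duplicate"
    parent_gene: str
    chrom: str
    start: int  # final coordinates of the copied CDS (0-based half-open)
    end: int
    strand: str
    intended_class: str  # "intact" | "pseudogene" | "na" (dna duplicates)
    chimeric: bool
    host_gene: str
    n_substitutions: int
    frameshift_positions: tuple[int, ...]  # bp offsets within the copied CDS
    stop_positions: tuple[int, ...]  # codon indices
    expressed: bool


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeAssembly
    models: list[GeneModel]
    proteins: list[ProteinRecord]
    ests: list[tuple[str, str]]
    truth: list[TruthEvent] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            d = dataclasses.asdict(t)
            d["frameshift_positions"] = ",".join(map(str, t.frameshift_positions))
            d["stop_positions"] = ",".join(map(str, t.stop_positions))
            rows.append(d)
        cols = [f.name for f in dataclasses.fields(TruthEvent)]
        return pd.DataFrame(rows, columns=cols)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "annotation": out / "annotation.gtf",
            "proteins": out / "proteins.fa",
            "ests": out / "ests.fa",
            "truth": out / "truth.tsv",
        }
        write_fasta(sorted(self.genome.sequences.items()), paths["genome"])
        write_gtf_cds(self.models, paths["annotation"])
        write_fasta([(p.protein_id, p.sequence) for p in self.proteins], paths["proteins"])
        write_fasta(self.ests, paths["ests"])
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    kappa: float,
    forbid_stops: bool,
) -> tuple[str, int]:
    """Apply uniform per-site substitutions; optionally re-draw any that
    create an in-frame stop codon (used for intact events, whose defining
    property is a preserved ORF)."""
    if rate == 0:
        return seq, 0
    arr = list(seq)
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        arr[i] = _substitute_base(rng, arr[i], kappa)
    if forbid_stops:
        for c0 in range(0, len(arr) - len(arr) % 3, 3):
            guard = 0
            while "".join(arr[c0 : c0 + 3]) in _STOPS:
                pos_in_codon = [i for i in hit if c0 <= i < c0 + 3]
                if not pos_in_codon:  # stop was present before mutation (impossible for sim CDS)
                    break
                i = int(rng.choice(pos_in_codon))
                arr[i] = _substitute_base(rng, seq[i], kappa)
                guard += 1
                if guard > 50:
                    raise SimulationError("could not avoid stop codon")
    return "".join(arr), int(hit.size)


def _substitute_base(rng: np.random.Generator, base: str, kappa: float) -> str:
    others = [b for b in "ACGT" if b != base]
    if kappa == 1.0:
        return others[rng.integers(0, 3)]
    w = np.array([kappa if b == _TRANSITION[base] else 1.0 for b in others])
    return others[rng.choice(3, p=w / w.sum())]


def _inject_premature_stop(
    rng: np.random.Generator, cds: str
) -> tuple[str, int] | None:
    """Point substitution creating TAA/TAG/TGA before 90% of the CDS.

    Returns (mutated cds, codon index) or None if no single-substitution
    stop is reachable in range (practically never for random CDSs).
    """
    n_codons = len(cds) // 3
    limit = max(2, int(n_codons * 0.9))
    candidates = []
    for ci in range(1, limit):
        codon = cds[ci * 3 : ci * 3 + 3]
        for stop in _STOPS:
            diff = [k for k in range(3) if codon[k] != stop[k]]
            if len(diff) == 1:
                candidates.append((ci, stop))
    if not candidates:
        return None
    ci, stop = candidates[rng.integers(0, len(candidates))]
    return cds[: ci * 3] + stop + cds[ci * 3 + 3 :], ci


def _inject_frameshift(rng: np.random.Generator, cds: str) -> tuple[str, int]:
    """Delete or insert 1-2 bp at a uniform CDS position."""
    size = int(rng.integers(1, 3))
    pos = int(rng.integers(3, len(cds) - 3 - size))
    if rng.random() < 0.5:
        return cds[:pos] + cds[pos + size :], pos
    ins = _random_dna(rng, size, 0.5)
    return cds[:pos] + ins + cds[pos:], pos


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # original (pre-insertion) coordinates
    exons: list[tuple[int, int]]
    cds: str  # spliced, transcript orientation
    introns: list[tuple[int, int]]  # genomic order


def _build_gene(rng: np.random.Generator, cfg: SimulationConfig, gene_id: str) -> tuple[str, list[int], list[int], str]:
    """Return (genomic gene sequence in transcript orientation,
    exon lengths, intron lengths, spliced CDS)."""
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    # exon lengths are drawn in whole codons (phase-0 introns)
    ex_lens = [
        3 * int(rng.integers(cfg.exon_length[0] // 3, cfg.exon_length[1] // 3 + 1))
        for _ in range(n_ex)
    ]
    cds = _random_cds(rng, sum(ex_lens) // 3)
    in_lens = [int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1)) for _ in range(n_ex - 1)]
    parts, off = [], 0
    for i, el in enumerate(ex_lens):
        parts.append(cds[off : off + el])
        off += el
        if i < n_ex - 1:
            interior = _random_dna(rng, in_lens[i] - 4, cfg.intergenic_gc)
            parts.append("GT" + interior + "AG")
    return "".join(parts), ex_lens, in_lens, cds


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full dataset in memory (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    names = cfg.chromosome_names()
    backgrounds = {n: _random_dna(rng, cfg.chromosome_length, cfg.intergenic_gc) for n in names}

    # --- place genes -------------------------------------------------------
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    genes: list[_Gene] = []
    margin = 50
    for gi in range(cfg.n_genes):
        gene_id = f"g{gi + 1:03d}"
        gseq, ex_lens, in_lens, cds = _build_gene(rng, cfg, gene_id)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _ in range(300):
            chrom = names[rng.integers(0, len(names))]
            L = cfg.chromosome_length
            if L - len(gseq) - 2 * margin <= 0:
                continue
            start = int(rng.integers(margin, L - len(gseq) - margin))
            iv = (start - margin, start + len(gseq) + margin)
            if any(a < iv[1] and iv[0] < b for a, b in occupied[chrom]):
                continue
            occupied[chrom].append((start, start + len(gseq)))
            placed = True
            break
        if not placed:
            raise SimulationError(
                "insufficient intergenic space to place genes; increase chromosome_length"
            )
        genomic = gseq if strand == "+" else reverse_complement(gseq)
        backgrounds[chrom] = (
            backgrounds[chrom][:start] + genomic + backgrounds[chrom][start + len(genomic) :]
        )
        # exon/intron genomic coordinates
        bounds = []  # (exon_start, exon_end) in transcript-oriented local coords
        off = 0
        for i, el in enumerate(ex_lens):
            bounds.append((off, off + el))
            off += el + (in_lens[i] if i < len(in_lens) else 0)
        glen = len(gseq)
        if strand == "+":
            exons = [(start + a, start + b) for a, b in bounds]
        else:
            exons = sorted((start + glen - b, start + glen - a) for a, b in bounds)
        introns = [(e1[1], e2[0]) for e1, e2 in zip(exons, exons[1:])]
        genes.append(_Gene(gene_id, chrom, strand, start, exons, cds, introns))

    gene_by_id = {g.gene_id: g for g in genes}
    gene_spans: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for g in genes:
        gene_spans[g.chrom].append((g.exons[0][0], g.exons[-1][1]))

    # --- retrotransposition / duplication events ---------------------------
    # each insertion: (original-coord position, full inserted string,
    #                  offset of copied CDS inside the insert, cds length, meta)
    insertions: dict[str, list[tuple[int, str, int, int, dict]]] = {n: [] for n in names}
    used_positions: dict[str, set[int]] = {n: set() for n in names}
    truth: list[TruthEvent] = []

    multi_exon = [g for g in genes if len(g.exons) >= 2]
    if (cfg.n_retro_events or cfg.n_dna_duplicates) and not multi_exon:
        raise SimulationError("no multi-exon genes to act as retro parents")

    def pick_intergenic(payload_len: int) -> tuple[str, int]:
        for _ in range(500):
            chrom = names[rng.integers(0, len(names))]
            pos = int(rng.integers(cfg.tsd_length + 1, cfg.chromosome_length - payload_len - 1))
            if any(a - 20 < pos < b + 20 for a, b in gene_spans[chrom]):
                continue
            if any(abs(pos - q) < 20 for q in used_positions[chrom]):
                continue
            used_positions[chrom].add(pos)
            return chrom, pos
        raise SimulationError(
            "insufficient intergenic space for insertions; increase chromosome_length"
        )

    for ei in range(cfg.n_retro_events):
        event_id = f"retro{ei + 1:03d}"
        parent = multi_exon[rng.integers(0, len(multi_exon))]
        chimeric = rng.random() < cfg.chimeric_prob
        host: _Gene | None = None
        if chimeric:
            hosts = [
                g
                for g in multi_exon
                if g.gene_id != parent.gene_id
                and any(b - a >= 30 for a, b in g.introns)
            ]
            if hosts:
                host = hosts[rng.integers(0, len(hosts))]
            else:
                chimeric = False

        fs_positions: list[int] = []
        stop_positions: list[int] = []
        if chimeric:
            # chimeric retrogenes are intact by definition
            cds_copy, n_subs = _mutate(rng, parent.cds, cfg.substitution_rate, cfg.kappa, True)
        else:
            disrupt_fs = rng.random() < cfg.frameshift_prob
            disrupt_stop = rng.random() < cfg.premature_stop_prob
            intact = not (disrupt_fs or disrupt_stop)
            cds_copy, n_subs = _mutate(
                rng, parent.cds, cfg.substitution_rate, cfg.kappa, forbid_stops=intact
            )
            if disrupt_stop:
                res = _inject_premature_stop(rng, cds_copy)
                if res is not None:
                    cds_copy, ci = res
                    stop_positions.append(ci)
            if disrupt_fs:
                cds_copy, pos = _inject_frameshift(rng, cds_copy)
                fs_positions.append(pos)
        intended = "pseudogene" if (fs_positions or stop_positions) else "intact"

        if host is not None:
            big = [iv for iv in host.introns if iv[1] - iv[0] >= 30]
            a, b = big[rng.integers(0, len(big))]
            pos = int(rng.integers(a + 5, b - 5))
            chrom, strand = host.chrom, host.strand
            used_positions[chrom].add(pos)
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, pos = pick_intergenic(len(cds_copy) + cfg.polya_length + cfg.tsd_length)

        body = cds_copy + "A" * cfg.polya_length
        if strand == "-":
            body = reverse_complement(body)
            cds_off = cfg.polya_length
        else:
            cds_off = 0
        tsd = backgrounds[chrom][max(0, pos - cfg.tsd_length) : pos]
        inserted = body + tsd  # duplicated target site flanks the insert
        meta = dict(
            event_id=event_id,
            kind="retro",
            parent_gene=parent.gene_id,
            strand=strand,
            intended_class=intended,
            chimeric=host is not None,
            host_gene=host.gene_id if host is not None else "",
            n_substitutions=n_subs,
            frameshift_positions=tuple(fs_positions),
            stop_positions=tuple(stop_positions),
        )
        insertions[chrom].append((pos, inserted, cds_off, len(cds_copy), meta))

    for di in range(cfg.n_dna_duplicates):
        event_id = f"dnadup{di + 1:03d}"
        parent = multi_exon[rng.integers(0, len(multi_exon))]
        gseq = backgrounds[parent.chrom][parent.exons[0][0] : parent.exons[-1][1]]
        chrom, pos = pick_intergenic(len(gseq))
        meta = dict(
            event_id=event_id,
            kind="dna_duplicate",
            parent_gene=parent.gene_id,
            strand=parent.strand,
            intended_class="na",
            chimeric=False,
            host_gene="",
            n_substitutions=0,
            frameshift_positions=(),
            stop_positions=(),
        )
        insertions[chrom].append((pos, gseq, 0, len(gseq), meta))

    # --- rebuild chromosomes with insertions, remap coordinates ------------
    final_seqs: dict[str, str] = {}
    shift_tables: dict[str, tuple[list[int], list[int]]] = {}
    for chrom in names:
        ins = sorted(insertions[chrom], key=lambda t: t[0])
        parts, prev, cum = [], 0, 0
        positions, cumlens = [], []
        for pos, seq, cds_off, cds_len, meta in ins:
            parts.append(backgrounds[chrom][prev:pos])
            new_start = pos + cum + cds_off
            truth.append(
                TruthEvent(
                    chrom=chrom,
                    start=new_start,
                    end=new_start + cds_len,
                    expressed=False,  # filled below
                    **meta,
                )
            )
            parts.append(seq)
            prev = pos
            cum += len(seq)
            positions.append(pos)
            cumlens.append(cum)
        parts.append(backgrounds[chrom][prev:])
        final_seqs[chrom] = "".join(parts)
        shift_tables[chrom] = (positions, cumlens)

    def shift(chrom: str, coord: int) -> int:
        positions, cumlens = shift_tables[chrom]
        i = bisect_right(positions, coord)
        return coord + (cumlens[i - 1] if i else 0)

    truth.sort(key=lambda t: (t.kind != "retro", t.event_id))

    models: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    for g in genes:
        exons = [(shift(g.chrom, a), shift(g.chrom, b - 1) + 1) for a, b in g.exons]
        models.append(
            GeneModel(
                gene_id=g.gene_id,
                transcript_id=f"t{g.gene_id[1:]}",
                chrom=g.chrom,
                strand=g.strand,
                exons=exons,
                protein_id=f"p{g.gene_id[1:]}",
            )
        )
        proteins.append(ProteinRecord(f"p{g.gene_id[1:]}", g.gene_id, translate(g.cds)))

    genome = GenomeAssembly(final_seqs)
    for n in names:
        genome.metadata[n].is_sex_chromosome = n == "chrX"

    # --- ESTs from expressed retrocopies -----------------------------------
    retro_truth = [t for t in truth if t.kind == "retro"]
    n_expr = int(round(cfg.expressed_fraction * len(retro_truth)))
    expr_idx = rng.choice(len(retro_truth), size=n_expr, replace=False) if n_expr else []
    for i in sorted(int(i) for i in np.atleast_1d(expr_idx)):
        retro_truth[i].expressed = True
    expressed = [t for t in retro_truth if t.expressed]

    ests: list[tuple[str, str]] = []
    if expressed and cfg.n_ests:
        for ri in range(cfg.n_ests):
            t = expressed[rng.integers(0, len(expressed))]
            lo = max(0, t.start - 50)
            hi = min(len(final_seqs[t.chrom]), t.end + 50)
            length = min(cfg.est_length, hi - lo)
            start = int(rng.integers(lo, hi - length + 1))
            read = final_seqs[t.chrom][start : start + length]
            if rng.random() < 0.5:
                read = reverse_complement(read)
            if cfg.est_error_rate > 0:
                arr = list(read)
                for j in np.flatnonzero(rng.random(len(arr)) < cfg.est_error_rate):
                    arr[j] = _substitute_base(rng, arr[j], 1.0)
                read = "".join(arr)
            ests.append((f"EST{ri + 1:05d}", read))

    ds = SimulatedDataset(
        config=cfg, genome=genome, models=models, proteins=proteins, ests=ests, truth=truth
    )
    _validate(ds)
    return ds


def _validate(ds: SimulatedDataset) -> None:
    from .io_formats import extract_cds

    for m in ds.models:
        prot = next(p for p in ds.proteins if p.protein_id == m.protein_id)
        cds = extract_cds(m, ds.genome)
        if translate(cds) != prot.sequence:
            raise SimulationError(f"annotation/genome mismatch for {m.gene_id}")
    for t in ds.truth:
        if t.intended_class == "pseudogene" and not (
            t.frameshift_positions or t.stop_positions
        ):
            raise SimulationError(f"{t.event_id}: pseudogene without disruption")
        if t.chimeric and (not t.host_gene or t.host_gene == t.parent_gene):
            raise SimulationError(f"{t.event_id}: bad chimeric host")


def expected_ks(
    substitution_rate: float,
    n_pairs: int = 200,
    n_codons: int = 300,
    seed: int = 0,
    kappa: float = 1.0,
) -> float:
    """Monte-Carlo expectation of NG86 Ks under the simulator's mutation
    model: generate random CDSs, mutate copies at the given per-site rate,
    and average the NG86 Ks estimates."""
    if substitution_rate == 0:
        return 0.0
    from .kaks import codon_pairs_from_cds, ng86

    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_pairs):
        cds = _random_cds(rng, n_codons)
        mut, _ = _mutate(rng, cds, substitution_rate, kappa, forbid_stops=False)
        res = ng86(codon_pairs_from_cds(cds, mut))
        if res.ks is not None:
            vals.append(res.ks)
    if not vals:
        raise SimulationError("all pairs saturated; rate too high")
    return float(np.mean(vals))
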