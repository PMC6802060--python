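"""Readers/writers and shared sequence/coordinate conventions.

All internal coordinates are 0-based half-open genomic intervals. Conversion
to/from 1-based inclusive coordinates happens only at the GTF boundary
(BED is already 0-based half-open). Only ``CDS`` features are consumed from
annotation files; a gene is represented by a single transcript (the one with
the longest CDS, ties broken by lexicographic transcript id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_DNA = set("ACGTN")


class FastaError(ValueError):
    """Malformed FASTA input (duplicate ids, empty records)."""


@dataclass
class ChromosomeInfo:
    """Metadata for one assembly sequence."""

    name: str
    length: int
    is_sex_chromosome: bool = False
    is_scaffold_or_mt: bool = False


@dataclass
class GenomeAssembly:
    """An in-memory genome: uppercase A/C/G/T/N sequences keyed by name."""

    sequences: dict[str, str]
    metadata: dict[str, ChromosomeInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if name not in self.metadata:
                self.metadata[name] = classify_chromosome(name, len(seq))
            if self.metadata[name].length != len(seq):
                raise ValueError(f"length mismatch for {name}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"{chrom}:{start}-{end} out of bounds (len {len(seq)})")
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        records = read_fasta(path)
        seqs = {}
        for name, seq in records:
            bad = set(seq) - _VALID_DNA
            if bad:
                raise ValueError(f"{name}: invalid DNA characters {sorted(bad)}")
            seqs[name] = seq
        return cls(seqs)


def classify_chromosome(name: str, length: int) -> ChromosomeInfo:
    """Heuristic chromosome metadata from the sequence name.

    ``chrX``/``X`` are sex chromosomes; names containing ``scaffold``,
    ``chrUn`` or ``MT``/``M`` are treated as unplaced/organellar.
    """
    base = name.removeprefix("chr")
    is_sex = base in {"X", "Y"}
    low = name.lower()
    is_scaf = (
        "scaffold" in low
        or low.startswith("chrun")
        or base in {"MT", "M"}
        or low.startswith(("ctg", "contig", "gl", "ki"))
    )
    return ChromosomeInfo(name, length, is_sex, is_scaf)


@dataclass
class GeneModel:
    """An annotated protein-coding gene (single representative transcript).

    ``exons`` are the ordered CDS exon intervals in genomic coordinates
    (0-based half-open, sorted by genomic start regardless of strand).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if b1 > a2:
                raise ValueError(f"{self.gene_id}: overlapping CDS exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def intron_positions_aa(self) -> list[float]:
        """Positions of introns along the protein, in amino-acid units.

        Returned in transcript (5'->3') order; an intron after the k-th
        coding base lies at protein coordinate k/3.
        """
        lens = [b - a for a, b in self.exons]
        if self.strand == "-":
            lens = lens[::-1]
        out, cum = [], 0
        for length in lens[:-1]:
            cum += length
            out.append(cum / 3.0)
        return out


@dataclass
class ProteinRecord:
    """A protein sequence tied to its gene."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty protein")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(id, uppercase sequence)`` pairs.

    The record id is the first whitespace-delimited token of the header.
    Duplicate ids and empty records raise :class:`FastaError`.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaError(f"empty FASTA record: {name}")
        records.append((name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FastaError("FASTA header with no id")
                if name in seen:
                    raise FastaError(f"duplicate FASTA id: {name}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise FastaError("sequence before first FASTA header")
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, val = part.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def read_annotation(path: str | Path, genome: GenomeAssembly | None = None) -> list[GeneModel]:
    """Read CDS rows from a GTF-style file into :class:`GeneModel` objects.

    GTF coordinates (1-based, inclusive) are converted to 0-based half-open.
    Only ``CDS`` features are used. When a gene carries several transcripts
    the longest CDS wins (ties: lexicographically smallest transcript id).
    Transcripts whose total CDS length is not divisible by 3 are excluded
    with a warning.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            chrom, _, _, start, end, _, strand, _, attr = fields[:9]
            attrs = _parse_gtf_attributes(attr)
            tx = attrs.get("transcript_id", attrs.get("gene_id", ""))
            rec = per_tx.setdefault(
                tx,
                {
                    "gene_id": attrs.get("gene_id", tx),
                    "chrom": chrom,
                    "strand": strand,
                    "protein_id": attrs.get("protein_id", ""),
                    "exons": [],
                },
            )
            if not rec["protein_id"] and attrs.get("protein_id"):
                rec["protein_id"] = attrs["protein_id"]
            iv = (int(start) - 1, int(end))
            if genome is not None:
                clen = genome.lengths.get(chrom)
                if clen is None or iv[1] > clen or iv[0] < 0:
                    raise ValueError(f"CDS {chrom}:{iv} outside assembly")
            rec["exons"].append(iv)

    models: list[GeneModel] = []
    for tx, rec in per_tx.items():
        total = sum(b - a for a, b in rec["exons"])
        if total % 3 != 0:
            logger.warning("transcript %s: CDS length %d not divisible by 3; excluded", tx, total)
            continue
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tx,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                protein_id=rec["protein_id"],
            )
        )

    # one transcript per gene: longest CDS, then lexicographic transcript id
    best: dict[str, GeneModel] = {}
    for m in sorted(models, key=lambda m: (-m.cds_length, m.transcript_id)):
        best.setdefault(m.gene_id, m)
    return sorted(best.values(), key=lambda m: (m.chrom, m.start, m.gene_id))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_cds(model: GeneModel, genome: GenomeAssembly) -> str:
    """Concatenate the CDS exons 5'->3' along the transcript."""
    parts = [genome.fetch(model.chrom, a, b) for a, b in model.exons]
    cds = "".join(parts)
    if model.strand == "-":
        cds = reverse_complement(cds)
    return cds


def translate(cds: str, strict: bool = False) -> str:
    """Translate a CDS with the standard genetic code.

    Codons containing N become ``X``; a trailing stop codon is stripped;
    in strict mode an internal stop raises ``ValueError``.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if strict and "*" in prot:
        raise ValueError(f"internal stop codon at aa {prot.index('*')}")
    return prot


def write_bed6(rows: Sequence[tuple[str, int, int, str, float, str]], path: str | Path) -> None:
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def write_gtf_cds(models: Iterable[GeneModel], path: str | Path, source: str = "retroforge") -> None:
    """Write GeneModels back out as GTF CDS rows (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            for a, b in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'protein_id "{m.protein_id}";'
                )
                fh.write(
                    f"{m.chrom}\t{source}\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t0\t{attrs}\n"
                )
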