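"""Codon-level evolution statistics: NG86 Ka/Ks, ω classes, Ks-based ages.

The estimator is the Nei–Gojobori (1986) counting method: fractional
synonymous/nonsynonymous site counts averaged over the two sequences,
observed differences averaged over all minimal mutational pathways
(pathways passing through stop codons are excluded; if every pathway is
blocked, all pathways are used), and a Jukes–Cantor multiple-hit
correction K = -(3/4)·ln(1 - (4/3)p). A proportion p ≥ 3/4 saturates the
correction and the corresponding rate is reported as undefined.

Ages follow the molecular-clock relation T = Ks / (2λ), with λ the
per-site per-year neutral substitution rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}
_DNA = set("ACGT")


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_clean(codon: str) -> bool:
    return len(codon) == 3 and set(codon) <= _DNA and codon not in _STOPS


@dataclass
class CodonAlignment:
    """Gap-free aligned codon pairs between a parent CDS and a retrocopy."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if not (_is_clean(a) and _is_clean(b)):
                raise ValueError(f"invalid codon pair {a}/{b}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def identity(self) -> float:
        if not self.pairs:
            return 0.0
        same = sum(a == b for a, b in self.pairs)
        return same / len(self.pairs)


@dataclass
class KaKsResult:
    """NG86 site/difference counts and corrected rates for one pair."""

    n_codons: int
    n_sites: float  # nonsynonymous sites N
    s_sites: float  # synonymous sites S
    nd: float
    sd: float
    pn: float
    ps: float
    ka: float | None  # None when saturated
    ks: float | None
    saturated_ka: bool = False
    saturated_ks: bool = False

    @property
    def omega(self) -> float | None:
        """Ka/Ks; undefined when Ks is 0 or either rate is saturated."""
        if self.ka is None or self.ks is None or self.ks == 0:
            return None
        return self.ka / self.ks


@dataclass
class DatingParams:
    """Neutral-rate calibration for Ks-based ages.

    The per-year rate derives from a per-generation rate and a generation
    time (defaults: 0.4e-8 per generation, 3-year generations, i.e.
    1.33e-9 per year — the canid calibration).
    """

    per_generation_rate: float = 0.4e-8
    generation_time_years: float = 3.0

    @property
    def lambda_per_year(self) -> float:
        return self.per_generation_rate / self.generation_time_years


def _syn_fraction(codon: str) -> float:
    """Fractional synonymous sites of one sense codon (changes to stop
    codons count as nonsynonymous)."""
    aa0 = _aa(codon)
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt not in _STOPS and _aa(alt) == aa0:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over minimal pathways
    between two codons, excluding pathways through stop codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every route passes a stop: fall back to all routes
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                if _aa(cur) == _aa(nxt) and nxt not in _STOPS and cur not in _STOPS:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when p ≥ 3/4 (saturated)."""
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(alignment: CodonAlignment | list[tuple[str, str]], min_codons: int = 1) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction."""
    pairs = alignment.pairs if isinstance(alignment, CodonAlignment) else list(alignment)
    L = len(pairs)
    if L < min_codons:
        raise ValueError(f"alignment of {L} codons < minimum {min_codons}")
    s_sites = 0.0
    sd = nd = 0.0
    for a, b in pairs:
        s_sites += (_syn_fraction(a) + _syn_fraction(b)) / 2.0
        dsd, dnd = _pair_differences(a, b)
        sd += dsd
        nd += dnd
    n_sites = 3.0 * L - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return KaKsResult(
        n_codons=L,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        saturated_ka=ka is None,
        saturated_ks=ks is None,
    )


def codon_pairs_from_cds(cds_a: str, cds_b: str) -> CodonAlignment:
    """Zip two equal-length in-frame CDSs into codon pairs, dropping any
    column containing a stop codon or ambiguity."""
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS lengths differ; use codon_align instead")
    pairs = []
    for i in range(0, len(cds_a) - len(cds_a) % 3, 3):
        a, b = cds_a[i : i + 3], cds_b[i : i + 3]
        if _is_clean(a) and _is_clean(b):
            pairs.append((a, b))
    return CodonAlignment(pairs)


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def codon_align(parent_cds: str, retro_cds: str) -> CodonAlignment:
    """Protein-guided codon alignment of a parent CDS and a retrocopy
    coding region.

    The conceptual translations are aligned globally (BLOSUM62, affine
    gaps), codons are back-threaded through the protein alignment, and
    gap columns plus columns containing stops or ambiguous bases are
    dropped.
    """
    pa = str(Seq(parent_cds[: len(parent_cds) - len(parent_cds) % 3]).translate())
    pb = str(Seq(retro_cds[: len(retro_cds) - len(retro_cds) % 3]).translate())
    if not pa or not pb:
        return CodonAlignment([])
    aln = _protein_aligner().align(pa.replace("X", "A"), pb.replace("X", "A"))[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            ia, ib = a0 + k, b0 + k
            ca = parent_cds[ia * 3 : ia * 3 + 3]
            cb = retro_cds[ib * 3 : ib * 3 + 3]
            if _is_clean(ca) and _is_clean(cb):
                pairs.append((ca, cb))
    return CodonAlignment(pairs)


def estimate_age(ks: float | None, params: DatingParams | None = None) -> float | None:
    """Age in Mya from Ks via T = Ks / (2λ); None for saturated Ks."""
    if ks is None:
        return None
    params = params or DatingParams()
    years = ks / (2.0 * params.lambda_per_year)
    return years / 1e6


def classify_selection(
    result: KaKsResult, constrained_max: float = 0.5, elevated_min: float = 1.2
) -> str:
    """Bin a pair by ω: constrained (ω < 0.5), intermediate (0.5 ≤ ω ≤ 1.2),
    elevated (ω > 1.2), or undefined (Ks zero/saturated)."""
    omega = result.omega
    if omega is None:
        return "undefined"
    if omega < constrained_max:
        return "constrained"
    if omega <= elevated_min:
        return "intermediate"
    return "elevated"


@dataclass
class KsHistogram:
    """Ks distribution with regular bins on [0,1) and pooled tails."""

    edges: list[tuple[float, float]]  # (left, right); right=inf for last
    counts: list[int]
    fractions: list[float] = field(default_factory=list)

    @property
    def modal_bin(self) -> tuple[float, float]:
        return self.edges[int(np.argmax(self.counts))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": [e[0] for e in self.edges],
                "bin_right": [e[1] for e in self.edges],
                "count": self.counts,
                "fraction": self.fractions,
            }
        )


def ks_histogram(ks_values: list[float], binwidth: float = 0.02) -> KsHistogram:
    """Histogram of Ks with bins of ``binwidth`` on [0,1) and two pooled
    bins [1,2) and [2,∞)."""
    vals = [k for k in ks_values if k is not None]
    n_regular = int(round(1.0 / binwidth))
    edges = [(i * binwidth, (i + 1) * binwidth) for i in range(n_regular)]
    edges += [(1.0, 2.0), (2.0, math.inf)]
    counts = [0] * len(edges)
    for k in vals:
        if k < 0:
            raise ValueError("negative Ks")
        if k < 1.0:
            counts[min(int(k / binwidth), n_regular - 1)] += 1
        elif k < 2.0:
            counts[n_regular] += 1
        else:
            counts[n_regular + 1] += 1
    total = max(1, len(vals))
    fractions = [c / total for c in counts]
    return KsHistogram(edges=edges, counts=counts, fractions=fractions)
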