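"""Hypergeometric gene-set enrichment and UAAU motif scanning.

Enrichment of a flagged gene list within a set of known bound targets is
assessed with the hypergeometric upper tail P(X >= k) for an overlap of k
when n genes are drawn from a background of N containing K marked genes.
Motif utilities scan 3'UTR sequences for the UAAU tetranucleotide bound by
Puf1/Puf2 and for the dual motif — two UAAU occurrences separated by a
short linker — and test multi-UAAU genes for enrichment against a
genome-wide background.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "MotifHits",
    "hypergeometric_tail",
    "gene_set_enrichment",
    "scan_uaau",
    "dual_motif",
    "multi_uaau_enrichment",
    "read_gmt",
    "write_gmt",
    "read_utr_fasta",
]

logger = logging.getLogger(__name__)

MOTIF = "UAAU"
_VALID_NT = re.compile(r"^[ACGTU]*$")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids (GMT-style)."""

    name: str
    members: frozenset = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of a sample within a marked subpopulation.

    population N, marked K, sample n, overlap k and the upper-tail
    p-value P(X >= k).
    """

    name: str
    population: int
    marked: int
    sample: int
    overlap: int
    p: float

    def summary(self) -> str:
        return (
            f"{self.name}: overlap {self.overlap}/{self.sample} drawn, "
            f"{self.marked} marked of {self.population} "
            f"(hypergeometric p = {self.p:.3g})"
        )


@dataclass(frozen=True)
class MotifHits:
    """UAAU occurrences in one sequence and qualifying dual pairs."""

    seq_id: str
    positions: tuple
    dual_pairs: tuple


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for hypergeometric(N, K, n), stable in log space.

    N: population size; K: marked items; n: sample size; k: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the pmf via log-gamma internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _depletion_tail(N: int, K: int, n: int, k: int) -> float:
    """Lower-tail P(X <= k)."""
    return float(stats.hypergeom.cdf(k, N, K, n))


def gene_set_enrichment(
    flagged: Iterable[str],
    target: GeneSet | Iterable[str],
    background: Iterable[str],
    depletion: bool = False,
) -> EnrichmentResult:
    """Hypergeometric enrichment of flagged genes within a target set.

    N = |background|, K = |target ∩ background|, n = |flagged|,
    k = |flagged ∩ target|.  Genes outside the background are dropped from
    both sets with a logged warning.  ``depletion=True`` tests the lower
    tail instead of the (default) enrichment upper tail.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    name = target.name if isinstance(target, GeneSet) else "target"
    tgt = set(target.members) if isinstance(target, GeneSet) else set(target)
    flg = set(flagged)
    for label, s in (("target", tgt), ("flagged", flg)):
        outside = s - bg
        if outside:
            logger.warning("%d %s gene(s) absent from background dropped: %s%s",
                           len(outside), label, sorted(outside)[:3],
                           "..." if len(outside) > 3 else "")
    tgt &= bg
    flg &= bg
    N, K, n, k = len(bg), len(tgt), len(flg), len(flg & tgt)
    p = _depletion_tail(N, K, n, k) if depletion else hypergeometric_tail(N, K, n, k)
    return EnrichmentResult(name=name, population=N, marked=K, sample=n,
                            overlap=k, p=p)


def _as_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    if not _VALID_NT.match(seq):
        bad = sorted(set(seq) - set("ACGU"))
        raise ValueError(f"non-nucleotide character(s): {bad}")
    return seq


def scan_uaau(sequence: str) -> list[int]:
    """All 0-based start positions of UAAU in a sequence, overlaps allowed.

    DNA input is transliterated T -> U first; the scan is strand-specific.
    """
    seq = _as_rna(sequence)
    positions = []
    start = seq.find(MOTIF)
    while start != -1:
        positions.append(start)
        start = seq.find(MOTIF, start + 1)
    return positions


def dual_motif(sequence: str, linker_min: int = 1, linker_max: int = 8) -> list[tuple[int, int]]:
    """Dual-UAAU pairs: consecutive UAAU occurrences separated by a linker.

    The linker of a pair (p1, p2) is p2 - (p1 + 4) and must lie in
    [linker_min, linker_max].  Only consecutive occurrences pair (a linker
    never contains the start of another UAAU), so a run of three motifs
    with qualifying gaps chains into two pairs.
    """
    if linker_min > linker_max:
        raise ValueError("linker_min > linker_max")
    pos = scan_uaau(sequence)
    pairs = []
    for p1, p2 in zip(pos, pos[1:]):
        linker = p2 - (p1 + len(MOTIF))
        if linker_min <= linker <= linker_max:
            pairs.append((p1, p2))
    return pairs


def multi_uaau_enrichment(
    target_genes: Iterable[str],
    utrs: Mapping[str, str],
    background_genes: Iterable[str],
    min_count: int = 2,
) -> EnrichmentResult:
    """Enrichment of genes with >= ``min_count`` UAAU motifs in their 3'UTR
    among target genes, relative to a genome-wide background.

    Every gene in the background must have a UTR sequence; missing genes
    are reported in the error.
    """
    bg = set(background_genes)
    tgt = set(target_genes)
    missing = sorted(g for g in bg | tgt if g not in utrs)
    if missing:
        raise KeyError(f"missing UTR sequence for {len(missing)} gene(s): {missing[:5]}")
    marked = {g for g in bg if len(scan_uaau(utrs[g])) >= min_count}
    return gene_set_enrichment(tgt, GeneSet(f">={min_count}xUAAU", marked), bg)


# ---------------------------------------------------------------------------
# file formats

def read_gmt(path) -> list[GeneSet]:
    """Read GMT gene sets (name <tab> description <tab> members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets.append(GeneSet(name=parts[0], description=parts[1],
                                members=frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_utr_fasta(path) -> dict[str, str]:
    """Read UTR sequences from FASTA, transliterating DNA T to RNA U."""
    from Bio import SeqIO

    return {rec.id: _as_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
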