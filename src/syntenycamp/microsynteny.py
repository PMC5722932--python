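"""Detection of microsyntenic two-gene clusters.

Microsynteny here means fine-scale conserved linkage: a gene of one family
lying next to a gene of a partner family on the same scaffold, with a small
intergenic gap, few or no interposed genes, and (by default) the same
transcription orientation.  Detection is a pure function of the annotation
and the criteria; results never depend on input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .genome_io import GeneRecord, GenomeAnnotation


@dataclass(frozen=True)
class PairCriteria:
    """Thresholds a candidate pair must satisfy.

    Defaults admit the largest intergenic distances seen in conserved
    vertebrate pairs (~200 kb) while rejecting same-chromosome placements
    separated by >1 Mb, and operationalize "no or very few genes
    interposed" as at most 3.
    """

    max_intergenic_bp: int = 500_000
    max_interposed: int = 3
    require_same_orientation: bool = True

    def __post_init__(self) -> None:
        if self.max_intergenic_bp <= 0:
            raise ValueError("max_intergenic_bp must be > 0")
        if self.max_interposed < 0:
            raise ValueError("max_interposed must be >= 0")


@dataclass(frozen=True)
class SyntenicPair:
    """A detected two-gene cluster and its descriptive quantities."""

    species: str
    gene_a: GeneRecord  # the PDI-family member
    gene_b: GeneRecord  # the RhoGDI-family member
    intergenic_distance_bp: int
    interposed_genes: int
    same_orientation: bool
    scaffold: str

    def __post_init__(self) -> None:
        if not (self.gene_a.scaffold == self.gene_b.scaffold == self.scaffold):
            raise ValueError("pair members must share the pair's scaffold")
        if self.intergenic_distance_bp < 0 or self.interposed_genes < 0:
            raise ValueError("distances and counts must be non-negative")

    @property
    def label(self) -> str:
        return f"{self.gene_a.gene_id}-{self.gene_b.gene_id}"


def intergenic_distance(g1: GeneRecord, g2: GeneRecord) -> int:
    """Base-pair gap between the facing boundaries of two genes.

    Zero for overlapping or book-ended genes; symmetric in argument order.
    The gap is the plain boundary difference (downstream start minus
    upstream end) without a −1 correction.
    """
    if g1.scaffold != g2.scaffold:
        raise ValueError(
            f"{g1.gene_id} and {g2.gene_id} are on different scaffolds "
            f"({g1.scaffold!r} vs {g2.scaffold!r})"
        )
    return max(0, max(g1.start, g2.start) - min(g1.end, g2.end))


def interposed_count(g1: GeneRecord, g2: GeneRecord, annotation: GenomeAnnotation) -> int:
    """Number of other genes lying between ``g1`` and ``g2``.

    A gene counts as interposed when its interval midpoint falls strictly
    between the facing boundaries of the two genes.
    """
    if g1.gene_id == g2.gene_id:
        raise ValueError(f"interposed_count of {g1.gene_id!r} against itself")
    for g in (g1, g2):
        if g.gene_id not in annotation:
            raise KeyError(f"gene {g.gene_id!r} not in annotation")
    if g1.scaffold != g2.scaffold:
        raise ValueError("genes on different scaffolds")
    upstream, downstream = sorted((g1, g2), key=lambda g: (g.start, g.end))
    lo, hi = upstream.end, downstream.start
    return sum(
        1
        for g in annotation.scaffold_genes(g1.scaffold)
        if g.gene_id not in (g1.gene_id, g2.gene_id) and lo < g.midpoint < hi
    )


def _satisfies(pair: SyntenicPair, criteria: PairCriteria) -> bool:
    if pair.intergenic_distance_bp > criteria.max_intergenic_bp:
        return False
    if pair.interposed_genes > criteria.max_interposed:
        return False
    if criteria.require_same_orientation and not pair.same_orientation:
        return False
    return True


def candidate_pairs(annotation: GenomeAnnotation) -> list[SyntenicPair]:
    """All same-scaffold (PDI-family, RhoGDI-family) gene combinations."""
    out = []
    for a in annotation.by_family("PDI"):
        for b in annotation.by_family("RhoGDI"):
            if a.scaffold != b.scaffold:
                continue
            out.append(
                SyntenicPair(
                    species=annotation.species,
                    gene_a=a,
                    gene_b=b,
                    intergenic_distance_bp=intergenic_distance(a, b),
                    interposed_genes=interposed_count(a, b, annotation),
                    same_orientation=a.strand == b.strand,
                    scaffold=a.scaffold,
                )
            )
    return out


def detect_pairs(
    annotation: GenomeAnnotation, criteria: PairCriteria = PairCriteria()
) -> list[SyntenicPair]:
    """Detect microsyntenic pairs satisfying ``criteria``.

    Each gene appears in at most one reported pair: where candidates
    compete for a gene, the smallest intergenic distance wins, ties broken
    by lexicographic gene IDs.  Output is sorted by (scaffold, leftmost
    start) and is independent of input row order.
    """
    passing = [p for p in candidate_pairs(annotation) if _satisfies(p, criteria)]
    passing.sort(
        key=lambda p: (p.intergenic_distance_bp, p.gene_a.gene_id, p.gene_b.gene_id)
    )
    used: set[str] = set()
    chosen = []
    for p in passing:
        if p.gene_a.gene_id in used or p.gene_b.gene_id in used:
            continue
        chosen.append(p)
        used.update((p.gene_a.gene_id, p.gene_b.gene_id))
    chosen.sort(key=lambda p: (p.scaffold, min(p.gene_a.start, p.gene_b.start)))
    return chosen


def format_kb(distance_bp: int) -> str:
    """Format a base-pair distance in kb at two significant figures, half-up.

    Matches the reporting convention of the human pair table: 142 bp →
    ``"0.14 kb"``, 2,935 bp → ``"2.9 kb"``, 7,027 bp → ``"7.0 kb"``.
    """
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    if distance_bp == 0:
        return "0 kb"
    kb = Decimal(distance_bp) / Decimal(1000)
    exponent = kb.adjusted()  # floor(log10(kb))
    quantum = Decimal(1).scaleb(exponent - 1)
    rounded = kb.quantize(quantum, rounding=ROUND_HALF_UP)
    # Re-quantize if rounding bumped the magnitude (e.g. 0.0995 -> 0.10).
    if rounded.adjusted() != exponent:
        rounded = kb.quantize(Decimal(1).scaleb(rounded.adjusted() - 1), rounding=ROUND_HALF_UP)
    text = format(rounded, "f")
    return f"{text} kb"
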