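"""Enhancer blocks, signed TSS distances, and CAMP calls.

A conserved ancestral microsyntenic pair (CAMP) is a syntenic gene pair
that additionally shares cis-regulatory evidence: at least one enhancer
block lying within a distance window of both genes' transcription start
sites.  Distances are signed by each gene's own transcription direction
(negative = upstream of the TSS).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from .genome_io import GeneRecord
from .microsynteny import SyntenicPair


@dataclass(frozen=True)
class EnhancerBlock:
    """A regulatory interval aggregating predicted enhancer evidence."""

    block_id: str
    scaffold: str
    start: int
    end: int
    associated_pair: str = ""
    consistent: bool = True  # False flags rows whose printed size contradicts the location

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"block {self.block_id!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TssDistancePair:
    """Signed kb distances of one block to the two genes of a pair."""

    block_id: str
    dist_gene1_kb: float
    dist_gene2_kb: float


@dataclass(frozen=True)
class CampCall:
    pair: str
    shared_blocks: tuple[str, ...]
    is_camp: bool

    def __post_init__(self) -> None:
        if self.is_camp != bool(self.shared_blocks):
            raise ValueError("is_camp must hold exactly when shared_blocks is non-empty")


def block_size_kb(block: EnhancerBlock) -> str:
    """Block size in kb at one decimal place, half-up (the printed convention).

    E.g. an 8,882 bp block formats as ``"8.9"``, a 399 bp block as ``"0.4"``.
    """
    kb = Decimal(block.size_bp) / Decimal(1000)
    return str(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tss_position(gene: GeneRecord) -> int:
    """Transcription start site: start for ``+`` genes, end for ``-`` genes."""
    return gene.start if gene.strand == "+" else gene.end


def signed_tss_distance_kb(block: EnhancerBlock, gene: GeneRecord) -> float:
    """Signed kb distance from the gene's TSS to the nearest block boundary.

    0.0 when the block spans the TSS.  Negative values place the block
    upstream of the TSS relative to the gene's transcription direction.
    """
    if block.scaffold != gene.scaffold:
        raise ValueError(
            f"block {block.block_id!r} on {block.scaffold!r} vs gene "
            f"{gene.gene_id!r} on {gene.scaffold!r}"
        )
    tss = tss_position(gene)
    if block.start <= tss <= block.end:
        return 0.0
    # distance to nearest boundary, then orient by strand
    if tss < block.start:
        dist = block.start - tss
        downstream = gene.strand == "+"
    else:
        dist = tss - block.end
        downstream = gene.strand == "-"
    return (dist if downstream else -dist) / 1000.0


def tss_distances(block: EnhancerBlock, pair: SyntenicPair) -> TssDistancePair:
    return TssDistancePair(
        block_id=block.block_id,
        dist_gene1_kb=signed_tss_distance_kb(block, pair.gene_a),
        dist_gene2_kb=signed_tss_distance_kb(block, pair.gene_b),
    )


def camp_call(
    pair: SyntenicPair,
    blocks: Iterable[EnhancerBlock],
    window_kb: float = 100.0,
) -> CampCall:
    """Call a pair a CAMP if >= 1 block is shared by both genes.

    A block is shared when its signed TSS distance has magnitude at most
    ``window_kb`` for *both* genes.  Blocks on other scaffolds never
    qualify.  The call is monotone in ``window_kb``.
    """
    shared = []
    for block in blocks:
        if block.scaffold != pair.scaffold:
            continue
        d1 = signed_tss_distance_kb(block, pair.gene_a)
        d2 = signed_tss_distance_kb(block, pair.gene_b)
        if abs(d1) <= window_kb and abs(d2) <= window_kb:
            shared.append(block.block_id)
    return CampCall(pair=pair.label, shared_blocks=tuple(shared), is_camp=bool(shared))
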