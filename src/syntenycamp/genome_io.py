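"""Readers and writers for gene tables (TSV/GFF3) and Newick trees.

All genomic coordinates are 1-based and inclusive on both ends, the
convention shared by GFF3 and by the human gene-position tables this
package ships as fixtures.  BED-style half-open input is not accepted
here; convert at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import dendropy

from .trees import SpeciesTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")
FAMILIES = ("PDI", "RhoGDI", "other")

TSV_COLUMNS = ("gene_id", "species", "scaffold", "start", "end", "strand", "group", "family")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One gene's genomic placement plus its species and ortholog-group label.

    ``start``/``end`` are 1-based inclusive base-pair positions; ``strand``
    is ``"+"`` or ``"-"``; ``family`` assigns the gene to one of the two
    partner families of a candidate microsyntenic pair (or ``"other"``).
    """

    gene_id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    group: str = ""
    family: str = "other"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.family not in FAMILIES:
            raise ValueError(
                f"gene {self.gene_id!r}: family must be one of {FAMILIES}, got {self.family!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class GenomeAnnotation:
    """An ordered, per-species collection of :class:`GeneRecord`.

    Genes are kept sorted by ``(scaffold, start, gene_id)`` regardless of
    construction order, and gene IDs must be unique.
    """

    def __init__(self, species: str, genes: Iterable[GeneRecord] = ()) -> None:
        self.species = species
        self._genes: list[GeneRecord] = sorted(
            genes, key=lambda g: (g.scaffold, g.start, g.gene_id)
        )
        self._by_id: dict[str, GeneRecord] = {}
        for g in self._genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in {species!r}")
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def genes(self) -> tuple[GeneRecord, ...]:
        return tuple(self._genes)

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation of {self.species!r}") from None

    def scaffold_genes(self, scaffold: str) -> tuple[GeneRecord, ...]:
        return tuple(g for g in self._genes if g.scaffold == scaffold)

    def by_group(self, group: str) -> tuple[GeneRecord, ...]:
        return tuple(g for g in self._genes if g.group == group)

    def by_family(self, family: str) -> tuple[GeneRecord, ...]:
        return tuple(g for g in self._genes if g.family == family)

    def strip_chr_prefix(self) -> "GenomeAnnotation":
        """Return a copy with a leading ``chr`` removed from scaffold names."""
        stripped = [
            replace(g, scaffold=g.scaffold[3:])
            if g.scaffold.lower().startswith("chr")
            else g
            for g in self._genes
        ]
        return GenomeAnnotation(self.species, stripped)

    def __repr__(self) -> str:
        return f"GenomeAnnotation({self.species!r}, {len(self)} genes)"


def _parse_tsv(path: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue  # header row
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 6 tab-separated fields, got {len(fields)}"
                )
            gene_id, species, scaffold, start, end, strand = fields[:6]
            group = fields[6] if len(fields) > 6 else ""
            family = fields[7] if len(fields) > 7 else "other"
            try:
                rec = GeneRecord(
                    gene_id=gene_id,
                    species=species,
                    scaffold=scaffold,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    group=group,
                    family=family or "other",
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def _parse_gff3(path: Path, species: str) -> list[GeneRecord]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted concrete errors
        raise ParseError(f"{path}: not parseable as GFF3: {exc}") from exc
    records = []
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise ParseError(f"{path}: gene feature without ID attribute at {feat.seqid}:{feat.start}")
        gene_id = feat.attributes["ID"][0]
        group = feat.attributes.get("group", [""])[0]
        family = feat.attributes.get("family", ["other"])[0]
        try:
            rec = GeneRecord(
                gene_id=gene_id,
                species=species,
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                group=group,
                family=family,
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        records.append(rec)
    return records


def read_gene_table(
    path: str | Path, dialect: str = "tsv", species: str | None = None
) -> GenomeAnnotation:
    """Read a gene annotation table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` — tab-separated ``gene_id species scaffold start end
        strand [group] [family]`` with optional header; or ``"gff3"`` —
        standard GFF3, genes only, ``ID`` attribute required (``group`` and
        ``family`` attributes are honoured if present).
    species
        Species label; required for GFF3 (the format carries none), and
        used as an override/check for TSV.
    """
    path = Path(path)
    if dialect == "tsv":
        records = _parse_tsv(path)
        if species is None:
            species = records[0].species if records else "unknown"
    elif dialect == "gff3":
        if species is None:
            raise ValueError("species= is required for the gff3 dialect")
        records = _parse_gff3(path, species)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'gff3'")
    if not records:
        logger.warning("no gene records read from %s", path)
    return GenomeAnnotation(species, records)


def write_gene_table(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write a :class:`GenomeAnnotation` in the TSV dialect (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for g in annotation:
            fh.write(
                "\t".join(
                    [g.gene_id, g.species, g.scaffold, str(g.start), str(g.end), g.strand, g.group, g.family]
                )
                + "\n"
            )


def read_newick(source: str | Path) -> SpeciesTree:
    """Read a single rooted Newick tree (path or literal Newick string).

    Leaf labels must be unique; polytomies are preserved as-is.
    """
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"not parseable as Newick: {exc}") from exc
    return SpeciesTree(tree)


@dataclass(frozen=True)
class RawEnhancerRow:
    block_id: str
    scaffold: str
    start: int
    end: int
    associated_pair: str = ""


def read_enhancer_table(path: str | Path, bed: bool = False) -> list[RawEnhancerRow]:
    """Read an enhancer-block TSV: ``block_id scaffold start end [pair]``.

    With ``bed=True`` the start column is taken as BED-style 0-based
    half-open and converted to 1-based inclusive on the way in.
    """
    rows: list[RawEnhancerRow] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "block_id":
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 fields")
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if bed:
                start += 1
            rows.append(
                RawEnhancerRow(
                    block_id=fields[0],
                    scaffold=fields[1],
                    start=start,
                    end=end,
                    associated_pair=fields[4] if len(fields) > 4 else "",
                )
            )
    return rows
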