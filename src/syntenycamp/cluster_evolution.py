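"""Cluster gain/loss/duplication history on a species phylogeny.

Ancestral cluster content is reconstructed under Dollo parsimony — the
cluster arrangement is gained exactly once and may only be lost thereafter
— which matches the single-origin argument these analyses make: a pair
arrangement conserved from cnidarians to vertebrates is far more plausibly
inherited than repeatedly reinvented.  Duplication counts come from
standard LCA-mapping reconciliation of a cluster (paralog) tree against
the species tree.

Nodes and edges are addressed by frozensets of descendant leaf labels
(see :mod:`.trees`); "the branch above clade X" and "clade X" are used
interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .genome_io import GenomeAnnotation
from .microsynteny import (
    PairCriteria,
    SyntenicPair,
    _satisfies,
    intergenic_distance,
    interposed_count,
)
from .trees import SpeciesTree

STATES = ("present", "absent", "unknown")

DISRUPTION_MODES = (
    "both_genes_lost",
    "one_gene_lost",
    "unlinked_same_scaffold",
    "unlinked_different_scaffold",
    "intact",
)


class PresenceMatrix:
    """Cluster state (present / absent / unknown) per species per cluster."""

    def __init__(self, df: pd.DataFrame) -> None:
        bad = set(df.values.ravel()) - set(STATES)
        if bad:
            raise ValueError(f"invalid states: {sorted(bad)}")
        self.df = df

    @classmethod
    def from_dict(
        cls, states: Mapping[str, Mapping[str, str]], clusters: Iterable[str], species: Iterable[str]
    ) -> "PresenceMatrix":
        clusters, species = list(clusters), list(species)
        df = pd.DataFrame("unknown", index=clusters, columns=species, dtype=object)
        for c, row in states.items():
            for s, st in row.items():
                df.loc[c, s] = st
        return cls(df)

    @property
    def clusters(self) -> list[str]:
        return list(self.df.index)

    @property
    def species(self) -> list[str]:
        return list(self.df.columns)

    def state(self, cluster: str, species: str) -> str:
        return self.df.loc[cluster, species]

    def leaves_in_state(self, cluster: str, state: str) -> frozenset[str]:
        row = self.df.loc[cluster]
        return frozenset(row.index[row == state])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="cluster")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="cluster"))

    def __eq__(self, other) -> bool:
        return isinstance(other, PresenceMatrix) and self.df.sort_index(axis=0).sort_index(axis=1).equals(
            other.df.sort_index(axis=0).sort_index(axis=1)
        )

    def __repr__(self) -> str:
        return f"PresenceMatrix({len(self.clusters)} clusters x {len(self.species)} species)"


@dataclass(frozen=True)
class DolloReconstruction:
    cluster: str
    gain_branch: frozenset[str]
    losses: frozenset[frozenset[str]]
    ancestral_state: Mapping[frozenset[str], str]


@dataclass(frozen=True)
class ReconciliationResult:
    duplication_nodes: frozenset[frozenset[str]]
    duplication_count: int
    lca_map: Mapping[frozenset[str], frozenset[str]]


@dataclass(frozen=True)
class DisruptionCall:
    species: str
    cluster: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in DISRUPTION_MODES:
            raise ValueError(f"invalid mode {self.mode!r}")


def build_presence_matrix(
    pairs_by_species: Mapping[str, Iterable[SyntenicPair]],
    cluster_members: Mapping[str, tuple[str, str]],
    missing_policy: str = "absent",
) -> PresenceMatrix:
    """Tabulate detected pairs into a cluster × species state matrix.

    ``cluster_members`` maps each cluster label to the (PDI-family group,
    RhoGDI-family group) pair defining it.  A species with no detected
    pair for a cluster gets ``missing_policy`` (``absent`` or ``unknown``).
    """
    if missing_policy not in ("absent", "unknown"):
        raise ValueError("missing_policy must be 'absent' or 'unknown'")
    member_sets = {c: frozenset(groups) for c, groups in cluster_members.items()}
    species = list(pairs_by_species)
    df = pd.DataFrame(missing_policy, index=list(cluster_members), columns=species, dtype=object)
    for sp, pairs in pairs_by_species.items():
        for pair in pairs:
            groups = frozenset((pair.gene_a.group, pair.gene_b.group))
            matches = [c for c, ms in member_sets.items() if ms == groups]
            if not matches:
                raise ValueError(
                    f"pair {pair.label} in {sp!r} has groups {sorted(groups)} "
                    "mapping to no cluster label"
                )
            df.loc[matches[0], sp] = "present"
    return PresenceMatrix(df)


def dollo_reconstruct(
    matrix: PresenceMatrix, tree: SpeciesTree, cluster: str
) -> DolloReconstruction:
    """Single-gain (Dollo) reconstruction of a cluster's history.

    The gain is placed on the branch above the MRCA of all ``present``
    leaves; losses are the minimal set of edges explaining every ``absent``
    leaf inside the gain clade.  ``unknown`` leaves constrain nothing.
    """
    present = matrix.leaves_in_state(cluster, "present") & tree.leaves
    absent = matrix.leaves_in_state(cluster, "absent") & tree.leaves
    if not present:
        raise ValueError(f"cluster {cluster!r} has no present leaf on this tree")
    gain = tree.mrca(present)

    losses: set[frozenset[str]] = set()
    ancestral: dict[frozenset[str], str] = {}

    def has_present(clade: frozenset[str]) -> bool:
        return bool(clade & present)

    def has_absent_signal(clade: frozenset[str]) -> bool:
        return bool(clade & absent)

    def walk(clade: frozenset[str]) -> None:
        # Called only for clades inside the gain subtree still carrying it.
        ancestral[clade] = "present"
        for child in tree.children(clade):
            if has_present(child):
                walk(child)
            elif has_absent_signal(child):
                losses.add(child)  # maximal all-non-present subtree with evidence
                for sub in _descendant_clades(tree, child):
                    ancestral[sub] = "absent"
                ancestral[child] = "absent"
            else:
                # all-unknown subtree: most parsimonious is retention
                for sub in _descendant_clades(tree, child):
                    ancestral[sub] = "present"
                ancestral[child] = "present"

    walk(gain)
    # nodes outside the gain clade never had the cluster
    for clade in tree.clades():
        ancestral.setdefault(clade, "absent")
    return DolloReconstruction(
        cluster=cluster,
        gain_branch=gain,
        losses=frozenset(losses),
        ancestral_state=ancestral,
    )


def _descendant_clades(tree: SpeciesTree, clade: frozenset[str]):
    for child in tree.children(clade):
        yield child
        yield from _descendant_clades(tree, child)


def reconcile_duplications(
    cluster_tree: SpeciesTree,
    species_tree: SpeciesTree,
    leaf_species_map: Mapping[str, str],
) -> ReconciliationResult:
    """LCA-mapping reconciliation of a cluster (paralog) tree.

    Every cluster-tree node maps to the species-tree MRCA of its leaves'
    species; an internal node is a duplication iff its image equals the
    image of at least one of its children.  Both trees must be rooted and
    binary.
    """
    for name, t in (("cluster", cluster_tree), ("species", species_tree)):
        if not t.is_binary():
            raise ValueError(
                f"{name} tree contains a polytomy; resolve it before reconciliation"
            )
    unmapped = cluster_tree.leaves - set(leaf_species_map)
    if unmapped:
        raise KeyError(f"cluster-tree leaves without species mapping: {sorted(unmapped)}")
    bad_species = set(leaf_species_map.values()) - species_tree.leaves
    if bad_species:
        raise KeyError(f"mapped species not in species tree: {sorted(bad_species)}")

    lca_map: dict[frozenset[str], frozenset[str]] = {}
    for clade in cluster_tree.clades():
        species = {leaf_species_map[leaf] for leaf in clade}
        lca_map[clade] = species_tree.mrca(species)

    dup_nodes = set()
    for clade in cluster_tree.clades():
        if cluster_tree.is_leaf(clade):
            continue
        children = cluster_tree.children(clade)
        if any(lca_map[clade] == lca_map[ch] for ch in children):
            dup_nodes.add(clade)
    return ReconciliationResult(
        duplication_nodes=frozenset(dup_nodes),
        duplication_count=len(dup_nodes),
        lca_map=lca_map,
    )


def classify_disruption(
    species: str,
    cluster: str,
    annotation: GenomeAnnotation,
    criteria: PairCriteria,
    cluster_members: Mapping[str, tuple[str, str]],
) -> DisruptionCall:
    """Audit a cluster's state in one species into loss vs. unlinking.

    ``intact`` if some gene pair from the cluster's two ortholog groups
    passes the criteria; otherwise the call distinguishes member loss from
    same- or different-scaffold unlinking.
    """
    group_a, group_b = cluster_members[cluster]
    genes_a = annotation.by_group(group_a)
    genes_b = annotation.by_group(group_b)
    if not genes_a and not genes_b:
        return DisruptionCall(species, cluster, "both_genes_lost")
    if not genes_a or not genes_b:
        return DisruptionCall(species, cluster, "one_gene_lost")
    same_scaffold = False
    for a in genes_a:
        for b in genes_b:
            if a.scaffold != b.scaffold:
                continue
            same_scaffold = True
            pair = SyntenicPair(
                species=species,
                gene_a=a,
                gene_b=b,
                intergenic_distance_bp=intergenic_distance(a, b),
                interposed_genes=interposed_count(a, b, annotation),
                same_orientation=a.strand == b.strand,
                scaffold=a.scaffold,
            )
            if _satisfies(pair, criteria):
                return DisruptionCall(species, cluster, "intact")
    mode = "unlinked_same_scaffold" if same_scaffold else "unlinked_different_scaffold"
    return DisruptionCall(species, cluster, mode)


def date_node(tree: SpeciesTree, node: Iterable[str]) -> float | None:
    """User-supplied age (million years) of a node, or None when unannotated.

    No age inference is performed; ages come solely from the tree's
    annotation table.
    """
    clade = frozenset(node)
    if not tree.has_clade(clade):
        raise KeyError(f"no node with leaf set {sorted(clade)}")
    return tree.ages.get(clade)
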