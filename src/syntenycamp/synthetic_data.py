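"""Forward simulation of gene-order evolution along a species tree.

The generative model mirrors the inferred history of a microsyntenic
two-gene cluster: a linked (PDI-family, RhoGDI-family) pair is gained once
on a designated branch, optionally duplicated en bloc on descendant
branches, and thereafter exposed to stochastic gene loss, segmental
inversion, single-gene translocation, and background gene insertion —
each a Poisson process with mean rate × branch length.  Every event is
logged, so the true presence/absence matrix, gain branch, and duplication
count are known exactly and recoverable by replay.

Model choices (units: rates are events per unit branch length):

* Gene loss acts per existing intact cluster: each cluster independently
  accrues Poisson(loss_rate × branch length) loss events, the first of
  which deletes one member gene and breaks the cluster.  Pair survival to
  a leaf therefore has the closed form exp(−loss_rate × path length from
  the gain).
* A duplication copies both member genes en bloc (order, strands,
  spacing) to a random genomic position, founding a new cluster label and
  new ortholog groups — paralogous clusters, not extra members.
* A translocation relocates a single gene to a distant position (another
  scaffold, or at least a few gene slots away), unlinking without loss.
* Cluster intactness is strict adjacency: members side by side on one
  scaffold, no interposed gene, same strand.  Any event that breaks this
  emits an explicit ``unlink`` event for the affected cluster.

All randomness flows through one ``numpy`` generator created from
``SimParams.seed``; a fixed seed makes the whole output bit-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .cluster_evolution import PresenceMatrix
from .genome_io import GeneRecord, GenomeAnnotation
from .trees import SpeciesTree

EVENT_TYPES = ("gain", "duplication", "loss", "inversion", "translocation", "insertion", "unlink")

PRIMORDIAL = "C0"


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; branches are clades (frozensets of leaves)."""

    gain_branch: frozenset
    duplication_branches: tuple = ()
    loss_rate: float = 0.0
    inversion_rate: float = 0.0
    translocation_rate: float = 0.0
    background_insertion_rate: float = 0.0
    n_background_genes: int = 20
    n_scaffolds: int = 2
    gene_length: int = 2_000
    intergene_spacing: int = 50_000
    cluster_gap: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "inversion_rate", "translocation_rate", "background_insertion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_background_genes < 0 or self.n_scaffolds < 1:
            raise ValueError("need n_background_genes >= 0 and n_scaffolds >= 1")


@dataclass(frozen=True)
class Event:
    """One recorded event, anchored to the branch above ``branch`` (a clade)."""

    type: str
    branch: frozenset
    cluster: str | None = None
    gene: str | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass(frozen=True)
class EventHistory:
    """Ordered event log; events on a branch appear in application order."""

    events: tuple[Event, ...]

    def on_branch(self, clade: frozenset) -> list[Event]:
        return [e for e in self.events if e.branch == clade]

    def of_type(self, *types: str) -> list[Event]:
        return [e for e in self.events if e.type in types]

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class SimOutput:
    annotations: Mapping[str, GenomeAnnotation]
    ortholog_table: Mapping[str, str]
    truth: EventHistory
    truth_matrix: PresenceMatrix
    cluster_members: Mapping[str, tuple[str, str]]


class _Gene:
    """Mutable in-flight gene (lineage id is stable across descendants)."""

    __slots__ = ("uid", "group", "family", "strand", "cluster", "role")

    def __init__(self, uid, group, family, strand, cluster=None, role=None):
        self.uid = uid
        self.group = group
        self.family = family
        self.strand = strand
        self.cluster = cluster
        self.role = role  # "pdi" | "gdi" | None

    def copy(self) -> "_Gene":
        return _Gene(self.uid, self.group, self.family, self.strand, self.cluster, self.role)


def _copy_genome(genome: list[list[_Gene]]) -> list[list[_Gene]]:
    return [[g.copy() for g in scaf] for scaf in genome]


def _intact_clusters(genome: list[list[_Gene]]) -> set[str]:
    """Clusters whose two members sit adjacent with equal strand."""
    intact = set()
    for scaf in genome:
        for a, b in zip(scaf, scaf[1:]):
            if (
                a.cluster is not None
                and a.cluster == b.cluster
                and {a.role, b.role} == {"pdi", "gdi"}
                and a.strand == b.strand
            ):
                intact.add(a.cluster)
    return intact


def _existing_clusters(genome: list[list[_Gene]]) -> set[str]:
    return {g.cluster for scaf in genome for g in scaf if g.cluster is not None}


class _Sim:
    def __init__(self, tree: SpeciesTree, params: SimParams):
        self.tree = tree
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.events: list[Event] = []
        self.uid_counter = itertools.count()
        self.cluster_counter = itertools.count(1)  # C0 is the gained cluster

    # -- helpers -------------------------------------------------------
    def _new_uid(self) -> int:
        return next(self.uid_counter)

    def _make_cluster_genes(self, cluster: str, strand: str) -> list[_Gene]:
        pdi = _Gene(self._new_uid(), f"PDI_{cluster}", "PDI", strand, cluster, "pdi")
        gdi = _Gene(self._new_uid(), f"GDI_{cluster}", "RhoGDI", strand, cluster, "gdi")
        return [pdi, gdi]

    def _random_slot(self, genome: list[list[_Gene]]) -> tuple[int, int]:
        s = int(self.rng.integers(len(genome)))
        pos = int(self.rng.integers(len(genome[s]) + 1))
        return s, pos

    def _random_safe_slot(self, genome: list[list[_Gene]]) -> tuple[int, int]:
        """A slot that does not fall between the two members of an intact pair.

        New clusters (gain, duplication) insert between existing loci, never
        inside another cluster; background insertions have no such guard.
        """
        for _ in range(50):
            s, pos = self._random_slot(genome)
            scaf = genome[s]
            if 0 < pos < len(scaf):
                a, b = scaf[pos - 1], scaf[pos]
                if a.cluster is not None and a.cluster == b.cluster:
                    continue
            return s, pos
        return 0, 0  # degenerate genomes only

    def _note_unlinks(self, genome, before: set[str], branch: frozenset, cause: str) -> None:
        after = _intact_clusters(genome)
        for c in sorted(before - after):
            if c in _existing_clusters(genome):
                self.events.append(Event("unlink", branch, cluster=c, detail=cause))

    # -- per-branch mutation -------------------------------------------
    def _apply_branch(self, clade: frozenset, genome: list[list[_Gene]]) -> None:
        p, rng = self.params, self.rng
        # the root has no real branch: no stochastic events accrue above it
        length = self.tree.edge_length(clade) if self.tree.parent(clade) is not None else 0.0

        if clade == p.gain_branch:
            strand = str(rng.choice(["+", "-"]))
            pair = self._make_cluster_genes(PRIMORDIAL, strand)
            s, pos = self._random_safe_slot(genome)
            genome[s][pos:pos] = pair
            self.events.append(Event("gain", clade, cluster=PRIMORDIAL))

        for dup_branch in p.duplication_branches:
            if dup_branch != clade:
                continue
            intact = sorted(_intact_clusters(genome))
            if not intact:
                raise ValueError(
                    f"duplication scheduled on branch {sorted(clade)} but no intact cluster exists"
                )
            source = intact[int(rng.integers(len(intact)))]
            new = f"C{next(self.cluster_counter)}"
            # locate source pair and copy it en bloc
            src_genes = None
            for scaf in genome:
                for i, g in enumerate(scaf):
                    if g.cluster == source and i + 1 < len(scaf) and scaf[i + 1].cluster == source:
                        src_genes = (scaf[i], scaf[i + 1])
                        break
                if src_genes:
                    break
            copies = []
            for g in src_genes:
                c = _Gene(self._new_uid(), f"{'PDI' if g.role == 'pdi' else 'GDI'}_{new}", g.family, g.strand, new, g.role)
                copies.append(c)
            s, pos = self._random_safe_slot(genome)
            genome[s][pos:pos] = copies
            self.events.append(Event("duplication", clade, cluster=new, detail=f"source={source}"))

        # gene loss: per existing cluster, Poisson events, each deleting a member
        for cluster in sorted(_existing_clusters(genome)):
            k = int(rng.poisson(p.loss_rate * length))
            for _ in range(k):
                members = [
                    (si, gi)
                    for si, scaf in enumerate(genome)
                    for gi, g in enumerate(scaf)
                    if g.cluster == cluster
                ]
                if not members:
                    break
                si, gi = members[int(rng.integers(len(members)))]
                gene = genome[si].pop(gi)
                self.events.append(
                    Event("loss", clade, cluster=cluster, gene=f"g{gene.uid}", detail=gene.role or "")
                )

        # inversions
        for _ in range(int(rng.poisson(p.inversion_rate * length))):
            s = int(rng.integers(len(genome)))
            scaf = genome[s]
            if len(scaf) < 2:
                continue
            i, j = sorted(rng.choice(len(scaf) + 1, size=2, replace=False))
            if j - i < 2:
                continue
            before = _intact_clusters(genome)
            segment = scaf[i:j][::-1]
            for g in segment:
                g.strand = "+" if g.strand == "-" else "-"
            scaf[i:j] = segment
            self.events.append(Event("inversion", clade, detail=f"scaffold={s},span=({i},{j})"))
            self._note_unlinks(genome, before, clade, "inversion")

        # translocations: relocate one gene to a distant slot
        for _ in range(int(rng.poisson(p.translocation_rate * length))):
            flat = [(si, gi) for si, scaf in enumerate(genome) for gi in range(len(scaf))]
            if not flat:
                continue
            si, gi = flat[int(rng.integers(len(flat)))]
            before = _intact_clusters(genome)
            gene = genome[si].pop(gi)
            for _try in range(20):
                s, pos = self._random_slot(genome)
                if s != si or abs(pos - gi) > 4:
                    break
            genome[s][pos:pos] = [gene]
            self.events.append(
                Event("translocation", clade, cluster=gene.cluster, gene=f"g{gene.uid}",
                      detail=f"from=({si},{gi}),to=({s},{pos})")
            )
            self._note_unlinks(genome, before, clade, "translocation")

        # background insertions
        for _ in range(int(rng.poisson(p.background_insertion_rate * length))):
            before = _intact_clusters(genome)
            uid = self._new_uid()
            strand = str(rng.choice(["+", "-"]))
            gene = _Gene(uid, f"g{uid}", "other", strand)
            s, pos = self._random_slot(genome)
            genome[s][pos:pos] = [gene]
            self.events.append(Event("insertion", clade, gene=f"g{uid}"))
            self._note_unlinks(genome, before, clade, "insertion")

    # -- emission ------------------------------------------------------
    def _emit_annotation(self, species: str, genome: list[list[_Gene]]) -> tuple[GenomeAnnotation, dict[str, str]]:
        p = self.params
        records, orthologs = [], {}
        for si, scaf in enumerate(genome):
            cursor = p.intergene_spacing
            prev: _Gene | None = None
            for g in scaf:
                if prev is not None:
                    gap = (
                        p.cluster_gap
                        if g.cluster is not None and g.cluster == prev.cluster
                        else p.intergene_spacing
                    )
                    cursor += gap
                gene_id = f"{species}_g{g.uid}"
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        species=species,
                        scaffold=f"scf{si}",
                        start=cursor,
                        end=cursor + p.gene_length - 1,
                        strand=g.strand,
                        group=g.group,
                        family=g.family,
                    )
                )
                orthologs[gene_id] = g.group
                cursor += p.gene_length
                prev = g
        return GenomeAnnotation(species, records), orthologs

    # -- driver --------------------------------------------------------
    def run(self) -> SimOutput:
        p, tree = self.params, self.tree
        clades = set(tree.clades())
        if p.gain_branch not in clades:
            raise ValueError(f"gain_branch {sorted(p.gain_branch)} is not an edge of the tree")
        for db in p.duplication_branches:
            if db not in clades:
                raise ValueError(f"duplication branch {sorted(db)} is not an edge of the tree")
            if not frozenset(db) <= p.gain_branch:
                raise ValueError("duplication branches must descend from (or equal) the gain branch")

        root_genome: list[list[_Gene]] = [[] for _ in range(p.n_scaffolds)]
        for i in range(p.n_background_genes):
            uid = self._new_uid()
            strand = "+" if i % 2 == 0 else "-"
            root_genome[i % p.n_scaffolds].append(_Gene(uid, f"g{uid}", "other", strand))

        annotations: dict[str, GenomeAnnotation] = {}
        ortholog_table: dict[str, str] = {}

        def descend(clade: frozenset, genome: list[list[_Gene]]) -> None:
            self._apply_branch(clade, genome)
            if tree.is_leaf(clade):
                (species,) = clade
                ann, orth = self._emit_annotation(species, genome)
                annotations[species] = ann
                ortholog_table.update(orth)
                return
            for child in tree.children(clade):
                descend(child, _copy_genome(genome))

        descend(tree.root, root_genome)

        truth = EventHistory(tuple(self.events))
        matrix = replay_truth(truth, tree)
        members = {
            c: (f"PDI_{c}", f"GDI_{c}")
            for c in sorted({e.cluster for e in truth if e.type in ("gain", "duplication")})
        }
        return SimOutput(
            annotations=annotations,
            ortholog_table=ortholog_table,
            truth=truth,
            truth_matrix=matrix,
            cluster_members=members,
        )


def simulate(tree: SpeciesTree, params: SimParams) -> SimOutput:
    """Evolve a root genome down ``tree`` under ``params`` (see module docs)."""
    return _Sim(tree, params).run()


def replay_truth(truth: EventHistory, tree: SpeciesTree) -> PresenceMatrix:
    """Presence/absence matrix implied by an event log, by state propagation.

    Only cluster-level events matter: ``gain`` and ``duplication`` create a
    cluster in the lineage; ``loss`` and ``unlink`` below remove it (a
    broken pair counts as absent-as-cluster).  Inconsistent histories
    (e.g. loss of a cluster the lineage never had) raise ``ValueError``.
    """
    clusters = sorted({e.cluster for e in truth if e.type in ("gain", "duplication")})
    gains = [e for e in truth if e.type == "gain"]
    if len({e.cluster for e in gains}) != len(gains):
        raise ValueError("inconsistent history: multiple gains of one cluster")

    states: dict[str, dict[str, str]] = {c: {} for c in clusters}

    def descend(clade: frozenset, present: set[str], ever: set[str]) -> None:
        present, ever = set(present), set(ever)
        for e in truth.on_branch(clade):
            if e.type in ("gain", "duplication"):
                if e.cluster in present:
                    raise ValueError(f"inconsistent history: {e.cluster} created twice in one lineage")
                present.add(e.cluster)
                ever.add(e.cluster)
            elif e.type in ("loss", "unlink"):
                if e.cluster is None:
                    continue  # rearrangement of a background gene
                if e.cluster not in ever:
                    raise ValueError(
                        f"inconsistent history: {e.type} of cluster {e.cluster} "
                        "that never existed on this lineage"
                    )
                present.discard(e.cluster)
        if tree.is_leaf(clade):
            (species,) = clade
            for c in clusters:
                states[c][species] = "present" if c in present else "absent"
            return
        for child in tree.children(clade):
            descend(child, present, ever)

    descend(tree.root, set(), set())
    return PresenceMatrix.from_dict(states, clusters, sorted(tree.leaves))


def cluster_gene_tree(truth: EventHistory, tree: SpeciesTree) -> tuple[SpeciesTree, dict[str, str]]:
    """Build the cluster (paralog) gene tree implied by an event history.

    Leaves are ``cluster@species`` for every cluster copy surviving to a
    leaf; duplications create bifurcations on the branch where they
    occurred; speciations bifurcate every lineage alive at the node.
    Extinct sub-lineages are pruned and unifurcations suppressed, so the
    result is binary whenever the species tree is.
    """
    gains = [e for e in truth if e.type == "gain"]
    if len(gains) != 1:
        raise ValueError("history must contain exactly one gain")
    gain = gains[0]

    def grow(clade: frozenset, label: str, ev_idx: int) -> str | None:
        branch_events = truth.on_branch(clade)
        for i in range(ev_idx, len(branch_events)):
            e = branch_events[i]
            if e.type in ("loss", "unlink") and e.cluster == label:
                return None  # lineage ends here (cluster gone/broken)
            if e.type == "duplication" and e.detail == f"source={label}":
                left = grow(clade, label, i + 1)
                right = grow(clade, e.cluster, i + 1)
                kids = [k for k in (left, right) if k is not None]
                if len(kids) == 2:
                    return f"({kids[0]},{kids[1]})"
                return kids[0] if kids else None
        if tree.is_leaf(clade):
            (species,) = clade
            return f"{label}@{species}"
        kids = []
        for child in tree.children(clade):
            sub = grow(child, label, 0)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return "(" + ",".join(kids) + ")"

    start_events = truth.on_branch(gain.branch)
    start_idx = start_events.index(gain) + 1
    newick = grow(gain.branch, gain.cluster, start_idx)
    if newick is None:
        raise ValueError("no cluster copy survives to any leaf")
    if "(" not in newick:
        newick = f"({newick})"
    gene_tree = SpeciesTree.from_newick(newick + ";")
    leaf_map = {leaf: leaf.split("@")[1] for leaf in gene_tree.leaves}
    return gene_tree, leaf_map
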