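"""Built-in fixtures: the published human PDI/RhoGDI data.

These are small literal transcriptions of the published human gene
coordinates (Table of gene locations), the predicted enhancer blocks
associated with the three pairs, and the species-level cluster
presence/absence pattern across eight animals, together with the species
phylogeny and the three-paralog cluster tree used for duplication
inference.

Conventions adopted here (documented assumptions):

* The shared "Sense reading" of each pair (Forward/Reverse) is taken as
  the strand of both genes: Forward → ``+``, Reverse → ``-``.  The source
  table states the two genes of a pair share transcription direction but
  does not list per-gene strands.
* The ARHGDIB end coordinate is printed with a truncated final digit
  ("14,961,72"); it is stored as 14,961,722.  No computed quantity in this
  package depends on it.
* Enhancer-block scaffolds are stored without the ``chr`` prefix so they
  are directly comparable with the gene table's scaffold names.
* Block GH12F014945 prints a 19.1 kb size against a 666 bp location span;
  it is flagged ``consistent=False`` and excluded from size checks.
"""

from __future__ import annotations

from .cluster_evolution import PresenceMatrix
from .genome_io import GeneRecord, GenomeAnnotation
from .regulatory_blocks import EnhancerBlock
from .trees import SpeciesTree

HUMAN = "H_sapiens"

#: cluster label -> (PDI-family ortholog group, RhoGDI-family ortholog group)
HUMAN_CLUSTERS: dict[str, tuple[str, str]] = {
    "PDIA1-RhoGDIa": ("PDIA1", "RhoGDIa"),
    "PDIA2-RhoGDIg": ("PDIA2", "RhoGDIg"),
    "PDIA8-RhoGDIb": ("PDIA8", "RhoGDIb"),
}

_TABLE1 = [
    # gene_id, scaffold, start, end, strand, group, family
    ("P4HB", "17", 81_843_159, 81_860_694, "-", "PDIA1", "PDI"),
    ("ARHGDIA", "17", 81_867_721, 81_871_406, "-", "RhoGDIa", "RhoGDI"),
    ("PDIA2", "16", 283_152, 287_215, "+", "PDIA2", "PDI"),
    ("ARHGDIG", "16", 268_727, 283_010, "+", "RhoGDIg", "RhoGDI"),
    ("ERP27", "12", 14_914_035, 14_939_082, "-", "PDIA8", "PDI"),
    ("ARHGDIB", "12", 14_942_017, 14_961_722, "-", "RhoGDIb", "RhoGDI"),
]

_TABLE2 = [
    # block_id, scaffold, start, end, associated_pair, consistent
    ("GH17F081864", "17", 81_864_502, 81_873_384, "P4HB-ARGHDIA", True),
    ("GH17F081857", "17", 81_857_580, 81_863_657, "P4HB-ARGHDIA", True),
    ("GH16F000333", "16", 333_802, 341_081, "PDIA2-ARGHDIG", True),
    ("GH16F000342", "16", 342_161, 343_428, "PDIA2-ARGHDIG", True),
    ("GH12F014927", "12", 14_927_767, 14_930_181, "ERP27-ARGHDIB", True),
    ("GH12F014937", "12", 14_937_141, 14_939_817, "ERP27-ARGHDIB", True),
    ("GH12F014945", "12", 15_111_199, 15_111_865, "ERP27-ARGHDIB", False),
    ("GH12F014975", "12", 14_975_401, 14_975_800, "ERP27-ARGHDIB", True),
]

#: published signed TSS distances (kb) per block, stored as data — these
#: come from a TSS annotation source external to the gene table and are
#: intentionally not recomputed from the fixture coordinates.
TABLE2_PRINTED_TSS_KB: dict[str, tuple[float, float]] = {
    "GH17F081864": (-8.3, 2.5),
    "GH17F081857": (0.1, 10.8),
    "GH16F000333": (54.3, 68.7),
    "GH16F000342": (59.7, 74.1),
    "GH12F014927": (10.1, 32.8),
    "GH12F014937": (0.6, 23.2),
    "GH12F014945": (-16.2, 6.4),
    "GH12F014975": (-36.5, -13.9),
}

#: printed block sizes (kb, one decimal) for the consistent rows
TABLE2_PRINTED_SIZES: dict[str, str] = {
    "GH17F081864": "8.9",
    "GH17F081857": "6.1",
    "GH16F000333": "7.3",
    "GH16F000342": "1.3",
    "GH12F014927": "2.4",
    "GH12F014937": "2.7",
    "GH12F014975": "0.4",
}

FIG1_SPECIES = [
    "H_sapiens",       # Sarcopterygii
    "L_oculatus",      # Actinopterygii (spotted gar, Holostei)
    "C_milii",         # Chondrichthyes (elephant shark)
    "S_purpuratus",    # Echinodermata
    "C_elegans",       # Nematoda
    "D_melanogaster",  # Arthropoda — cluster disrupted (> 1 Mb apart)
    "N_vectensis",     # Cnidaria
    "A_queenslandica", # Porifera — orthologs unlinked
]

FIG1_NEWICK = (
    "(A_queenslandica,(N_vectensis,((C_elegans,D_melanogaster),"
    "(S_purpuratus,(C_milii,(H_sapiens,L_oculatus))))));"
)

VERTEBRATES = frozenset({"H_sapiens", "L_oculatus", "C_milii"})
CNIDARIAN_BILATERIAN_CLADE = frozenset(FIG1_SPECIES) - {"A_queenslandica"}

#: age annotation (million years) for the cnidarian+bilaterian ancestor
FIG1_AGES = {CNIDARIAN_BILATERIAN_CLADE: 820.0}

# species-level cluster states transcribed from the published figures/text:
# the primordial pair is found from cnidarians through bilaterians, is
# disrupted in the fly and unlinked in the sponge; the three paralogous
# clusters are vertebrate-specific, with the PDIA8/RhoGDIb cluster poorly
# conserved (not found in the elephant shark, not reported for the gar).
_FIG1_STATES = {
    "primordial": {
        "H_sapiens": "present",
        "L_oculatus": "present",
        "C_milii": "present",
        "S_purpuratus": "present",
        "C_elegans": "present",
        "D_melanogaster": "absent",
        "N_vectensis": "present",
        "A_queenslandica": "absent",
    },
    "PDIA1-RhoGDIa": {
        "H_sapiens": "present",
        "L_oculatus": "present",
        "C_milii": "present",
        "S_purpuratus": "absent",
        "C_elegans": "absent",
        "D_melanogaster": "absent",
        "N_vectensis": "absent",
        "A_queenslandica": "absent",
    },
    "PDIA2-RhoGDIg": {
        "H_sapiens": "present",
        "L_oculatus": "present",
        "C_milii": "present",
        "S_purpuratus": "absent",
        "C_elegans": "absent",
        "D_melanogaster": "absent",
        "N_vectensis": "absent",
        "A_queenslandica": "absent",
    },
    "PDIA8-RhoGDIb": {
        "H_sapiens": "present",
        "L_oculatus": "unknown",
        "C_milii": "absent",
        "S_purpuratus": "absent",
        "C_elegans": "absent",
        "D_melanogaster": "absent",
        "N_vectensis": "absent",
        "A_queenslandica": "absent",
    },
}

# Three-paralog cluster tree over the three vertebrate species, one leaf
# per (cluster, species).  The paralog nesting (PDIA1,(PDIA8,PDIA2)) is
# read from the published paralog trees; duplication inference yields two
# duplications at the vertebrate ancestor under either sister resolution.
def _cluster_tree_newick(nesting: str = "PDIA1-first") -> str:
    def sub(c: str) -> str:
        return f"({c}@C_milii,({c}@H_sapiens,{c}@L_oculatus))"

    a1, a2, a8 = "PDIA1-RhoGDIa", "PDIA2-RhoGDIg", "PDIA8-RhoGDIb"
    if nesting == "PDIA1-first":
        return f"({sub(a1)},({sub(a8)},{sub(a2)}));"
    # alternative resolution: PDIA2 splits first
    return f"({sub(a2)},({sub(a8)},{sub(a1)}));"


def cluster_tree_fig2(nesting: str = "PDIA1-first") -> tuple[SpeciesTree, dict[str, str]]:
    """The three-paralog cluster tree and its leaf→species map."""
    tree = SpeciesTree.from_newick(_cluster_tree_newick(nesting))
    leaf_map = {leaf: leaf.split("@")[1] for leaf in tree.leaves}
    return tree, leaf_map


def builtin_fixture(name: str):
    """Return a registered fixture object by name.

    ``human_table1`` → :class:`GenomeAnnotation` of the six human genes;
    ``enhancers_table2`` → list of the eight :class:`EnhancerBlock`;
    ``species_presence_fig1`` → :class:`PresenceMatrix` over eight species;
    ``species_tree_fig1`` → :class:`SpeciesTree` (with the 820 My age
    annotation on the cnidarian+bilaterian ancestor);
    ``cluster_tree_fig2`` → (cluster tree, leaf→species map).
    """
    if name == "human_table1":
        genes = [
            GeneRecord(
                gene_id=gid,
                species=HUMAN,
                scaffold=scaf,
                start=start,
                end=end,
                strand=strand,
                group=group,
                family=family,
            )
            for gid, scaf, start, end, strand, group, family in _TABLE1
        ]
        return GenomeAnnotation(HUMAN, genes)
    if name == "enhancers_table2":
        return [
            EnhancerBlock(
                block_id=bid,
                scaffold=scaf,
                start=start,
                end=end,
                associated_pair=pair,
                consistent=ok,
            )
            for bid, scaf, start, end, pair, ok in _TABLE2
        ]
    if name == "species_presence_fig1":
        return PresenceMatrix.from_dict(_FIG1_STATES, list(_FIG1_STATES), FIG1_SPECIES)
    if name == "species_tree_fig1":
        return SpeciesTree.from_newick(FIG1_NEWICK, ages=FIG1_AGES)
    if name == "cluster_tree_fig2":
        return cluster_tree_fig2()
    raise KeyError(
        f"unknown fixture {name!r}; registered: human_table1, enhancers_table2, "
        "species_presence_fig1, species_tree_fig1, cluster_tree_fig2"
    )
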