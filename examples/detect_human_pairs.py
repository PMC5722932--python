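"""Detect the three human PDI/RhoGDI microsyntenic pairs.

Loads the packaged human gene-coordinate fixture and runs pair detection
under the default criteria (<= 500 kb intergenic gap, <= 3 interposed
genes, same transcription orientation).
"""

from syntenycamp import builtin_fixture, detect_pairs, format_kb

annotation = builtin_fixture("human_table1")
pairs = detect_pairs(annotation)

print(f"detected {len(pairs)} microsyntenic pairs in {annotation.species}:")
for p in pairs:
    print(
        f"  chr{p.scaffold}: {p.gene_a.gene_id} ({p.gene_a.group}) / "
        f"{p.gene_b.gene_id} ({p.gene_b.group})  gap {format_kb(p.intergenic_distance_bp)}, "
        f"{p.interposed_genes} interposed, same orientation: {p.same_orientation}"
    )

# Each line is one tight two-gene cluster: a PDI-family gene directly
# flanked by a RhoGDI-family gene.  The kb figures are the base-pair gaps
# between the facing gene boundaries at two significant figures.
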