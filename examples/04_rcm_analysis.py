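"""Reverse-complementary-match (RCM) analysis of circRNA-flanking introns.

Plants 30-nt RCMs into the flanking introns of 80% of circRNA loci, then
searches intron pairs with word-size-7 seed-and-extend and tests enrichment
of RCM counts at circRNA loci against exon-2 and exon-8 control loci from
non-circRNA genes (Kruskal-Wallis with Dunn's post-hoc).
"""

import pandas as pd

from circage import features_rcm, simulate

cfg = simulate.SimConfig(
    n_genes=60, exons_per_gene=(4, 10), n_circ_genes=20,
    rcm_fraction=0.8, rcm_length=30, rng_seed=1,
)
genome, genes = simulate.generate_genome_and_annotation(cfg)
loci = simulate.plan_circ_loci(genes, cfg)
genome, planted = simulate.plant_rcms(genome, genes, loci, cfg)
gmap = {g.gene_id: g for g in genes}

rows = []
for locus in loci:
    up, down = features_rcm.flanking_introns_by_index(
        gmap[locus.gene_id], locus.first_idx, locus.last_idx, genome
    )
    hits = features_rcm.find_rcms(up, down)
    rows.append(features_rcm.locus_rcm_summary(locus.gene_id, "circ", hits))

circ_gene_ids = {l.gene_id for l in loci}
for rank, label in ((2, "control_exon2"), (8, "control_exon8")):
    for c in features_rcm.select_control_loci(genes, circ_gene_ids, rank, len(loci), seed=1):
        up, down = features_rcm.flanking_introns_by_index(
            gmap[c.gene_id], c.genomic_index, c.genomic_index, genome
        )
        rows.append(features_rcm.locus_rcm_summary(
            f"{c.gene_id}_e{rank}", label, features_rcm.find_rcms(up, down)
        ))

summ = pd.DataFrame(rows)
print(f"planted RCMs at {len(planted)}/{len(loci)} circ loci (30 nt)")
print("\nmean RCM hits per locus group:")
print(summ.groupby("locus_type")["n_hits"].agg(["mean", "count"]).to_string())

report = features_rcm.rcm_enrichment_test(summ)
print(f"\nKruskal-Wallis: H = {report['H']:.1f}, p = {report['p']:.2e}")
print("Dunn post-hoc p-values (Bonferroni-adjusted):")
print(report["dunn"].round(6).to_string())
print("circRNA-flanking introns carry far more RCMs than position-matched "
      "controls, the base-pairing signature that promotes circularization.")
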