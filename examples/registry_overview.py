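"""Survey the zebrafish CYP gene complement and its tandem duplication arrays."""

import cypwaves as cw

registry = cw.load_registry()  # packaged table, Zv8 / Ensembl 58 coordinates

print(f"rows: {len(registry)}  distinct genes: {cw.count_genes(registry)}  "
      f"families: {cw.count_families(registry)}")
# 96 table rows collapse to 94 genes (two loci appear twice as assembly copies)
# spread over 18 CYP families.

for family in (1, 2, 3, 4):
    print(f"  CYP{family}: {cw.count_genes(registry, family=family)} genes")

print("\nTandem arrays (single-linkage, max gap 100 kb):")
for chrom, subfamily in [("3", "2K"), ("23", "2AA"), ("20", None)]:
    kwargs = {"subfamily": subfamily} if subfamily else {"family": 2}
    for cluster in cw.tandem_clusters(registry, chromosome=chrom, **kwargs):
        if cluster.size > 1:
            mb = (cluster.span[1] - cluster.span[0]) / 1e6
            print(f"  chr{cluster.chromosome}: {cluster.size} genes over "
                  f"{mb:.2f} Mb  ({', '.join(cluster.members[:4])}...)")
# The CYP2K array on chromosome 3 (8 genes), the CYP2AA array on chromosome 23
# (10 genes), and the CYP2J-like cluster on chromosome 20 (11 genes across the
# 2N/2AD/2V/2P subfamilies) are local duplication hotspots of the CYP2 family.
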